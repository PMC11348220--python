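"""Pre-training orchestration: model bundle, training loop, checkpoints.

The trainer is a scikit-learn style estimator: constructor parameters are
stored verbatim, :meth:`GraphImagePretrainer.fit` consumes paired graphs and
images, and fitted state lives in trailing-underscore attributes
(``model_``, ``history_``, ``vocab_``). Each epoch samples one image view
per molecule, mini-batches the pairs, and descends the sum of the four
objectives (contrastive alignment, masked-attribute prediction, hard-negative
matching, cross-modal generative matching) with Adam.

Checkpoints are NPZ files holding every parameter tensor plus a JSON echo of
the model configuration; save -> load -> encode is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import nn, objectives
from .encoders import GINConfig, GraphBatch, GraphEncoder, ImageEncoder, \
    ImageEncoderConfig, ProjectionHeads
from .graphs import AttributeVocabulary, MolecularGraph, mask_graph
from .images import CellImage
from .nn import Adam, Tensor
from .objectives import EmbeddingPairBatch, FusionHead, GMHeads, MatchBatch, \
    MgmHead, LossReport
from .retrieval import RetrievalReport, evaluate_pairs

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "CrossModalModel",
    "GraphImagePretrainer",
    "pretrain",
    "finetune_property",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_SCHEMA = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture; defaults follow the reference setup (5 GIN layers, 300 dims)."""

    gin_layers: int = 5
    hidden_dim: int = 300
    embed_dim: int = 300
    shared_dim: int = 256
    head_hidden: int = 64
    image_size: int = 128
    in_channels: int = 5
    conv_widths: tuple[int, ...] = (8, 16, 32)
    node_vocab_sizes: tuple[int, ...] = (119,)
    edge_vocab_sizes: tuple[int, ...] = (4,)
    readout: str = "sum"
    seed: int = 0

    def vocabulary(self) -> AttributeVocabulary:
        return AttributeVocabulary(tuple(self.node_vocab_sizes),
                                   tuple(self.edge_vocab_sizes))


@dataclass
class TrainConfig:
    """Optimization settings; learning rate / weight decay default to the
    reference recipe (Adam, 3e-4, 0.02)."""

    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 3e-4
    weight_decay: float = 0.02
    loss_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    temperature: float = 0.1
    lambda_kl: float = 0.1
    mask_rate: float = 0.15
    neg_per_pos: int = 1  # GIM negatives per positive pair
    margin_gamma: float = 4.0  # accepted for config compatibility; unused
    similarity: str = "cosine"
    val_fraction: float = 0.1
    eval_every: int = 0  # epochs between held-out retrieval evals; 0 = never
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (contrastive negatives)")
        if self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("invalid optimization settings")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be nonnegative")


class CrossModalModel:
    """Both encoders, the projection heads and all loss heads, in one bundle."""

    def __init__(self, config: ModelConfig):
        self.config = config
        vocab = config.vocabulary()
        self.graph_encoder = GraphEncoder(GINConfig(
            config.gin_layers, config.hidden_dim, vocab, config.readout,
            seed=config.seed))
        self.image_encoder = ImageEncoder(ImageEncoderConfig(
            config.in_channels, config.embed_dim, tuple(config.conv_widths),
            image_size=config.image_size, seed=config.seed + 1))
        self.projection = ProjectionHeads(config.hidden_dim, config.embed_dim,
                                          config.shared_dim,
                                          seed=config.seed + 2)
        self.mgm_head = MgmHead(config.hidden_dim, config.embed_dim,
                                vocab.node_vocab_sizes, vocab.edge_vocab_sizes,
                                hidden=config.head_hidden,
                                seed=config.seed + 3)
        self.fusion_head = FusionHead(config.shared_dim,
                                      hidden=config.head_hidden,
                                      seed=config.seed + 4)
        self.gm_heads = GMHeads(config.hidden_dim, config.embed_dim,
                                hidden=config.head_hidden,
                                seed=config.seed + 5)

    def params(self) -> dict[str, Tensor]:
        out = self.graph_encoder.params()
        out.update(self.image_encoder.params())
        out.update(self.projection.params())
        out.update(self.mgm_head.params())
        out.update(self.fusion_head.params())
        out.update(self.gm_heads.params())
        return out

    # inference helpers (numpy in, numpy out)
    def encode_graphs(self, graphs: Sequence[MolecularGraph]) -> np.ndarray:
        return self.graph_encoder.encode(list(graphs)).data

    def encode_images(self, images: Sequence[CellImage]) -> np.ndarray:
        return self.image_encoder.encode(list(images)).data


def save_checkpoint(model: CrossModalModel, path: str | Path,
                    extra: dict | None = None) -> None:
    cfg = {"schema": CHECKPOINT_SCHEMA, "model": asdict(model.config),
           "extra": extra or {}}
    arrays = {k: p.data for k, p in model.params().items()}
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> CrossModalModel:
    with np.load(path) as npz:
        cfg = json.loads(bytes(npz["__config__"]).decode())
        if cfg.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema: {cfg.get('schema')}")
        mc = cfg["model"]
        for key in ("conv_widths", "node_vocab_sizes", "edge_vocab_sizes"):
            mc[key] = tuple(mc[key])
        model = CrossModalModel(ModelConfig(**mc))
        params = model.params()
        for k, p in params.items():
            p.data = np.asarray(npz[k], dtype=np.float64).copy()
    return model


def infer_vocabulary(graphs: Sequence[MolecularGraph]) -> AttributeVocabulary:
    """Smallest vocabulary covering the observed attribute indices."""
    d_n = graphs[0].node_attrs.shape[1]
    d_e = graphs[0].edge_attrs.shape[1]
    node_max = np.zeros(d_n, dtype=int)
    edge_max = np.ones(d_e, dtype=int)
    for g in graphs:
        node_max = np.maximum(node_max, g.node_attrs.max(axis=0))
        if g.num_arcs:
            edge_max = np.maximum(edge_max, g.edge_attrs.max(axis=0))
    return AttributeVocabulary(tuple(int(m) + 1 for m in node_max),
                               tuple(int(m) + 1 for m in edge_max))


class GraphImagePretrainer(BaseEstimator):
    """Cross-modal contrastive pre-trainer (scikit-learn style estimator).

    Parameters mirror :class:`ModelConfig` + :class:`TrainConfig`; the
    defaults here are desk-scale (2 GIN layers, 16 dims) so that fitting on
    a synthetic dataset takes seconds to minutes on one CPU. After
    :meth:`fit`, ``model_`` holds the trained bundle, ``history_`` the
    per-epoch loss reports (and periodic held-out retrieval reports), and
    ``transform_graphs`` / ``transform_images`` produce embeddings.
    """

    def __init__(self, gin_layers: int = 2, hidden_dim: int = 16,
                 embed_dim: int = 16, shared_dim: int = 16,
                 head_hidden: int = 32, image_size: int = 32,
                 epochs: int = 30, batch_size: int = 32,
                 learning_rate: float = 3e-4, weight_decay: float = 0.02,
                 loss_weights: tuple = (1.0, 1.0, 1.0, 1.0),
                 temperature: float = 0.1, lambda_kl: float = 0.1,
                 mask_rate: float = 0.15, neg_per_pos: int = 1,
                 margin_gamma: float = 4.0, similarity: str = "cosine",
                 val_fraction: float = 0.1, eval_every: int = 0,
                 readout: str = "sum", seed: int = 0):
        self.gin_layers = gin_layers
        self.hidden_dim = hidden_dim
        self.embed_dim = embed_dim
        self.shared_dim = shared_dim
        self.head_hidden = head_hidden
        self.image_size = image_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.loss_weights = loss_weights
        self.temperature = temperature
        self.lambda_kl = lambda_kl
        self.mask_rate = mask_rate
        self.neg_per_pos = neg_per_pos
        self.margin_gamma = margin_gamma
        self.similarity = similarity
        self.val_fraction = val_fraction
        self.eval_every = eval_every
        self.readout = readout
        self.seed = seed

    # -- fitting ------------------------------------------------------------
    def fit(self, graphs: Sequence[MolecularGraph],
            images: Sequence[CellImage]) -> "GraphImagePretrainer":
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        graphs = list(graphs)
        images = list(images)
        if not graphs or not images:
            raise ValueError("empty dataset")
        by_mol: dict[str, list[CellImage]] = {}
        for im in images:
            by_mol.setdefault(im.molecule_id, []).append(im)
        graph_ids = {g.molecule_id for g in graphs}
        orphans = [m for m in by_mol if m not in graph_ids]
        if orphans:
            raise ValueError(f"images reference unknown molecules: {orphans[:5]}")
        paired = [g for g in graphs if g.molecule_id in by_mol]
        if not paired:
            raise ValueError("no (graph, image) pairs to train on")

        self.vocab_ = infer_vocabulary(paired)
        first = by_mol[paired[0].molecule_id][0]
        self.model_ = CrossModalModel(ModelConfig(
            gin_layers=self.gin_layers, hidden_dim=self.hidden_dim,
            embed_dim=self.embed_dim, shared_dim=self.shared_dim,
            head_hidden=self.head_hidden,
            image_size=first.pixels.shape[-1],
            in_channels=first.num_channels,
            node_vocab_sizes=self.vocab_.node_vocab_sizes,
            edge_vocab_sizes=self.vocab_.edge_vocab_sizes,
            readout=self.readout, seed=self.seed))

        # independent streams per randomness source, all derived from `seed`,
        # so disabling one objective cannot perturb the draws of another
        ss = np.random.SeedSequence(self.seed)
        rng, rng_mask, rng_gim, rng_gm = (np.random.default_rng(c)
                                          for c in ss.spawn(4))
        self._obj_rngs = (rng_mask, rng_gim, rng_gm)
        mols = sorted(g.molecule_id for g in paired)
        n_val = int(round(self.val_fraction * len(mols)))
        val_ids = set(rng.choice(mols, size=n_val, replace=False)) if n_val \
            else set()
        self.val_molecules_ = sorted(val_ids)
        train_graphs = [g for g in paired if g.molecule_id not in val_ids]
        if len(train_graphs) < 2:
            raise ValueError("need at least two training molecules")
        graph_by_id = {g.molecule_id: g for g in paired}

        params = self.model_.params()
        opt = Adam(params, lr=self.learning_rate,
                   weight_decay=self.weight_decay)
        self.history_ = []
        w = dict(zip(("gic", "mgm", "gim", "gm"), self.loss_weights))
        step = 0
        for epoch in range(self.epochs):
            order = rng.permutation(len(train_graphs))
            epoch_reports: list[LossReport] = []
            for start in range(0, len(order), self.batch_size):
                idx = order[start:start + self.batch_size]
                if len(idx) < 2:
                    continue
                batch_graphs = [train_graphs[i] for i in idx]
                batch_images = [by_mol[g.molecule_id][
                    rng.integers(len(by_mol[g.molecule_id]))]
                    for g in batch_graphs]
                loss, report = self._batch_loss(batch_graphs, batch_images,
                                                w, rng, step)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_reports.append(report)
                step += 1
            entry = {"epoch": epoch,
                     "loss": _mean_report(epoch_reports)}
            if (self.eval_every and (epoch + 1) % self.eval_every == 0
                    and self.val_molecules_):
                entry["retrieval"] = self.evaluate(
                    [graph_by_id[m] for m in self.val_molecules_],
                    [im for m in self.val_molecules_ for im in by_mol[m]],
                    seed=self.seed).to_dict()
            self.history_.append(entry)
        return self

    def _batch_loss(self, batch_graphs, batch_images, w, rng, step):
        rng_mask, rng_gim, rng_gm = self._obj_rngs
        model = self.model_
        k = len(batch_graphs)
        zg = model.graph_encoder.encode(batch_graphs)
        zi = model.image_encoder.encode(batch_images)
        pg = model.projection.project_graph(zg)
        pi = model.projection.project_image(zi)
        comps: dict[str, Tensor | float] = {}
        if w["gic"] > 0:
            comps["gic"] = objectives.gic_loss(EmbeddingPairBatch(
                pg, pi, self.temperature, self.similarity))
        if w["mgm"] > 0 and self.mask_rate > 0:
            masked, specs = [], []
            for g in batch_graphs:
                m, s = mask_graph(g, self.mask_rate, self.vocab_,
                                  int(rng_mask.integers(2**31)))
                masked.append(m)
                specs.append(s)
            if not all(s.is_empty for s in specs):
                comps["mgm"] = objectives.mgm_loss(
                    masked, specs, zi, model.graph_encoder, model.mgm_head)
        if w["gim"] > 0:
            sim = objectives.similarity_matrix(pg, pi, self.similarity).data
            neg_img = objectives.sample_hard_negatives(sim, rng_gim)
            neg_gr = objectives.sample_hard_negatives(sim.T, rng_gim)
            n_neg = max(1, int(round(self.neg_per_pos * k)))
            neg_rows_g, neg_rows_i = [], []
            for j in range(n_neg):
                i = j % k
                if j % 2 == 0:  # graph_i with a hard-negative image
                    neg_rows_g.append(i)
                    neg_rows_i.append(int(neg_img[i]))
                else:  # image_i with a hard-negative graph
                    neg_rows_g.append(int(neg_gr[i]))
                    neg_rows_i.append(i)
            g_idx = np.concatenate([np.arange(k), neg_rows_g])
            i_idx = np.concatenate([np.arange(k), neg_rows_i])
            probs = model.fusion_head.match_probability(pg[g_idx], pi[i_idx])
            labels = np.concatenate([np.ones(k), np.zeros(n_neg)])
            comps["gim"] = objectives.gim_loss(MatchBatch(probs, labels))
        if w["gm"] > 0:
            comps["gm"] = objectives.gm_loss(zg, zi, model.gm_heads,
                                             self.lambda_kl, rng=rng_gm)
        try:
            return objectives.total_loss(comps, w)
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"non-finite loss at step {step}: {exc}") from exc

    # -- inference ----------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")

    def transform_graphs(self, graphs: Sequence[MolecularGraph],
                         projected: bool = False) -> np.ndarray:
        self._check_fitted()
        z = self.model_.graph_encoder.encode(list(graphs))
        return (self.model_.projection.project_graph(z).data if projected
                else z.data)

    def transform_images(self, images: Sequence[CellImage],
                         projected: bool = False) -> np.ndarray:
        self._check_fitted()
        z = self.model_.image_encoder.encode(list(images))
        return (self.model_.projection.project_image(z).data if projected
                else z.data)

    def evaluate(self, graphs: Sequence[MolecularGraph],
                 images: Sequence[CellImage],
                 direction: str = "image_retrieval", neg_per_pos: int = 100,
                 seed: int = 0, ks: Sequence[int] = (1, 5, 10),
                 projected: bool = False) -> RetrievalReport:
        """Held-out paired-retrieval metrics in the raw embedding space."""
        self._check_fitted()
        graphs = list(graphs)
        images = list(images)
        gz = self.transform_graphs(graphs, projected)
        iz = self.transform_images(images, projected)
        gmap = {g.molecule_id: z for g, z in zip(graphs, gz)}
        ilist = [(im.molecule_id, z) for im, z in zip(images, iz)]
        avail = len(images) - min(
            sum(1 for im in images if im.molecule_id == g.molecule_id)
            for g in graphs)
        neg = min(neg_per_pos, avail)
        return evaluate_pairs(gmap, ilist, direction, neg, seed, ks)


def _mean_report(reports: list[LossReport]) -> dict:
    if not reports:
        return LossReport().to_dict()
    keys = ("gic", "mgm", "gim", "gm", "total")
    out = {k: float(np.mean([getattr(r, k) for r in reports])) for k in keys}
    out["weights"] = list(reports[0].weights)
    return out


def pretrain(graphs: Sequence[MolecularGraph], images: Sequence[CellImage],
             config: TrainConfig, model_config: ModelConfig | None = None,
             checkpoint_path: str | Path | None = None
             ) -> tuple[GraphImagePretrainer, list[dict]]:
    """Functional wrapper over :class:`GraphImagePretrainer`."""
    mc = model_config or ModelConfig()
    est = GraphImagePretrainer(
        gin_layers=mc.gin_layers, hidden_dim=mc.hidden_dim,
        embed_dim=mc.embed_dim, shared_dim=mc.shared_dim,
        head_hidden=mc.head_hidden, image_size=mc.image_size,
        epochs=config.epochs, batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        weight_decay=config.weight_decay,
        loss_weights=tuple(config.loss_weights),
        temperature=config.temperature, lambda_kl=config.lambda_kl,
        mask_rate=config.mask_rate, neg_per_pos=config.neg_per_pos,
        margin_gamma=config.margin_gamma, similarity=config.similarity,
        val_fraction=config.val_fraction, eval_every=config.eval_every,
        readout=mc.readout, seed=config.seed)
    est.fit(graphs, images)
    if checkpoint_path is not None:
        save_checkpoint(est.model_, checkpoint_path,
                        extra={"train": asdict(config)})
    return est, est.history_


def finetune_property(model: CrossModalModel | str | Path | None,
                      labeled: Sequence[tuple[MolecularGraph, int]],
                      epochs: int = 200, learning_rate: float = 1e-2,
                      freeze_encoder: bool = True, val_fraction: float = 0.2,
                      seed: int = 0,
                      encoder_config: GINConfig | None = None
                      ) -> tuple[dict, float]:
    """Train a binary property classifier on top of the graph encoder.

    ``model`` may be a trained bundle, a checkpoint path, or None (randomly
    initialized encoder — the transfer-learning control). Returns the
    classifier state and the held-out ROC AUC.
    """
    from sklearn.metrics import roc_auc_score

    labeled = list(labeled)
    labels = np.array([int(y) for _, y in labeled])
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    if isinstance(model, (str, Path)):
        model = load_checkpoint(model)
    if model is not None:
        encoder = model.graph_encoder
    else:
        encoder = GraphEncoder(encoder_config or GINConfig(
            num_layers=2, hidden_dim=16,
            vocab=infer_vocabulary([g for g, _ in labeled]), seed=seed))

    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(labeled))
    n_val = max(1, int(round(val_fraction * len(labeled))))
    # stratified-ish: retry shuffles until both splits see both classes
    for _ in range(100):
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        if len(np.unique(labels[tr_idx])) == 2 and len(tr_idx) >= 2:
            break
        idx = rng.permutation(len(labeled))
    head = nn.Linear(encoder.config.hidden_dim, 1, np.random.default_rng(seed))
    params = head.params("head.")
    if not freeze_encoder:
        params.update(encoder.params())
    opt = Adam(params, lr=learning_rate)
    tr_graphs = [labeled[i][0] for i in tr_idx]
    tr_y = Tensor(labels[tr_idx].astype(float))
    batch = GraphBatch(tr_graphs)
    for _ in range(epochs):
        if freeze_encoder:
            z = Tensor(encoder.graph_embeddings(batch).data)
        else:
            z = encoder.graph_embeddings(batch)
        p = head(z).reshape(len(tr_graphs)).sigmoid().clip(1e-7, 1 - 1e-7)
        loss = -(tr_y * p.log() + (1.0 - tr_y) * (1.0 - p).log()).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    def predict(graphs_):
        z = encoder.encode(list(graphs_)).data
        return 1.0 / (1.0 + np.exp(-(z @ head.weight.data[:, 0]
                                     + head.bias.data[0])))
    val_graphs = [labeled[i][0] for i in val_idx]
    val_scores = predict(val_graphs)
    tr_scores = predict(tr_graphs)
    auc = float(roc_auc_score(labels[val_idx], val_scores)) \
        if len(np.unique(labels[val_idx])) == 2 else float("nan")
    state = {"head_weight": head.weight.data.copy(),
             "head_bias": head.bias.data.copy(),
             "train_accuracy": float(np.mean((tr_scores > 0.5)
                                             == labels[tr_idx])),
             "predict": predict}
    return state, auc
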