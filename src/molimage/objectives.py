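"""The four pre-training objectives and their sum.

* GIC — graph-image contrastive learning: a symmetric InfoNCE loss over a
  batch of matched (graph, image) pairs projected into the common space.
  Matched pairs are the positive class of a temperature-scaled softmax over
  the batch; both retrieval directions are averaged.
* MGM — masked graph modeling: categorical cross-entropy of predicting the
  masked atom/bond attributes from the observed-graph node context fused
  with the paired image embedding.
* GIM — graph-image matching: binary cross-entropy of a fusion head that
  classifies (graph, image) pairs as matched or not, with in-batch hard
  negatives sampled in proportion to contrastive similarity.
* GM — generative matching: a pair of cross-modal variational autoencoders,
  each asked to recover one modality's embedding from the other's; the loss
  is the negative ELBO (unit-variance Gaussian reconstruction + weighted
  closed-form diagonal-Gaussian KL to a standard-normal prior).

All losses are pure functions of tensors (plus head parameters) returning a
scalar :class:`~molimage.nn.Tensor`, so analytic gradients come from the
shared autodiff and can be checked against finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .encoders import GraphBatch, GraphEncoder
from .graphs import MaskSpec, MolecularGraph
from .nn import MLP, Tensor, concat, logsumexp

__all__ = [
    "EmbeddingPairBatch",
    "MatchBatch",
    "LossReport",
    "MgmHead",
    "FusionHead",
    "GMHeads",
    "similarity_matrix",
    "gic_loss",
    "mgm_loss",
    "sample_hard_negatives",
    "gim_loss",
    "gaussian_kl",
    "gm_loss",
    "total_loss",
]

CLAMP_EPS = 1e-7


@dataclass
class EmbeddingPairBatch:
    """K matched rows of projected graph/image vectors plus τ and similarity."""

    graph_proj: Tensor
    image_proj: Tensor
    temperature: float = 0.1
    similarity: str = "cosine"  # or "euclidean"

    def __post_init__(self):
        self.graph_proj = nn.as_tensor(self.graph_proj)
        self.image_proj = nn.as_tensor(self.image_proj)
        if self.graph_proj.shape[0] != self.image_proj.shape[0]:
            raise ValueError("graph/image row counts differ")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.similarity not in ("cosine", "euclidean"):
            raise ValueError(f"unknown similarity {self.similarity!r}")

    @property
    def size(self) -> int:
        return self.graph_proj.shape[0]


def _l2_normalize(x: Tensor) -> Tensor:
    norm = ((x * x).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
    return x / norm


def similarity_matrix(a: Tensor, b: Tensor, kind: str = "cosine") -> Tensor:
    """(K, K) similarities between rows of a and rows of b.

    ``euclidean`` returns negative squared L2 distance, so that larger is
    always more similar.
    """
    a, b = nn.as_tensor(a), nn.as_tensor(b)
    if kind == "cosine":
        return _l2_normalize(a) @ _l2_normalize(b).T
    if kind == "euclidean":
        a2 = (a * a).sum(axis=1, keepdims=True)
        b2 = (b * b).sum(axis=1, keepdims=True)
        return (a @ b.T) * 2.0 - a2 - b2.T
    raise ValueError(f"unknown similarity {kind!r}")


def _info_nce_direction(logits: Tensor) -> Tensor:
    """Mean cross-entropy with the diagonal as the positive class."""
    k = logits.shape[0]
    pos = logits[np.arange(k), np.arange(k)]
    return (logsumexp(logits, axis=1) - pos).mean()


def gic_loss(batch: EmbeddingPairBatch, literal_denominator: bool = False
             ) -> Tensor:
    """Symmetric InfoNCE over a batch of matched pairs.

    Default form scales every similarity by τ and includes the positive in
    the softmax normalizer, so the loss is nonnegative and equals log K when
    all similarities are equal. ``literal_denominator=True`` switches to the
    variant that excludes the matched pair from the normalizer and applies τ
    to the numerator only.
    """
    if batch.size < 2:
        raise ValueError("contrastive loss needs K >= 2 (no negatives otherwise)")
    sim = similarity_matrix(batch.graph_proj, batch.image_proj, batch.similarity)
    tau = batch.temperature
    k = batch.size
    if literal_denominator:
        off = Tensor(np.where(np.eye(k, dtype=bool), -np.inf, 0.0))
        terms = []
        for logits in (sim, sim.T):
            pos = logits[np.arange(k), np.arange(k)] * (1.0 / tau)
            denom = logsumexp(logits + off, axis=1)
            terms.append((denom - pos).mean())
        return (terms[0] + terms[1]) * 0.5
    logits = sim * (1.0 / tau)
    return (_info_nce_direction(logits) + _info_nce_direction(logits.T)) * 0.5


# ---------------------------------------------------------------------------
# MGM


class MgmHead:
    """Predicts masked attributes from (node context, image embedding).

    One single-hidden-layer perceptron per attribute vocabulary; masked-bond
    prediction consumes the sum of the two endpoint node representations.
    """

    def __init__(self, node_dim: int, image_dim: int,
                 node_vocab_sizes: Sequence[int],
                 edge_vocab_sizes: Sequence[int],
                 hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        in_dim = node_dim + image_dim
        self.node_heads = [MLP([in_dim, hidden, s], rng) for s in node_vocab_sizes]
        self.edge_heads = [MLP([in_dim, hidden, s], rng) for s in edge_vocab_sizes]

    def params(self, prefix: str = "mgm.") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for j, h in enumerate(self.node_heads):
            out.update(h.params(f"{prefix}node{j}."))
        for j, h in enumerate(self.edge_heads):
            out.update(h.params(f"{prefix}edge{j}."))
        return out


def _masked_ce(logits: Tensor, targets: np.ndarray) -> Tensor:
    return (logsumexp(logits, axis=1)
            - logits[np.arange(len(targets)), targets]).sum()


def mgm_loss(masked_graphs: Sequence[MolecularGraph],
             specs: Sequence[MaskSpec],
             image_embeddings: Tensor,
             encoder: GraphEncoder,
             head: MgmHead) -> Tensor:
    """Mean cross-entropy over all masked node and bond positions in a batch.

    The masked graphs are run through the GIN so each masked position sees
    only observed context; its final-layer representation is concatenated
    with the paired image embedding and scored against the true attribute.
    """
    image_embeddings = nn.as_tensor(image_embeddings)
    if len(masked_graphs) != len(specs):
        raise ValueError("graphs and mask specs length mismatch")
    if all(s.is_empty for s in specs):
        raise ValueError("no masked positions in batch; skip MGM for it")
    batch = GraphBatch(list(masked_graphs))
    h = encoder.node_embeddings(batch)

    total = Tensor(0.0)
    count = 0
    # gather masked node rows with per-graph offsets, tiling z_I per position
    node_rows, node_imgs, node_tgts = [], [], []
    bond_u, bond_v, bond_imgs, bond_tgts = [], [], [], []
    for i, (g, s) in enumerate(zip(masked_graphs, specs)):
        off = batch.node_offsets[i]
        for idx, tgt in zip(s.masked_node_indices, s.node_targets):
            node_rows.append(off + idx)
            node_imgs.append(i)
            node_tgts.append(tgt)
        # one prediction per masked bond (arcs are stored in inverse pairs)
        arcs = np.asarray(s.masked_edge_indices).reshape(-1, 2)[:, 0] \
            if len(s.masked_edge_indices) else []
        for a_local, tgt in zip(arcs, s.edge_targets[::2]):
            u, v = g.edge_index[a_local]
            bond_u.append(off + u)
            bond_v.append(off + v)
            bond_imgs.append(i)
            bond_tgts.append(tgt)
    if node_rows:
        ctx = concat([h[np.asarray(node_rows)],
                      image_embeddings[np.asarray(node_imgs)]], axis=1)
        tgts = np.asarray(node_tgts)
        for j, head_j in enumerate(head.node_heads):
            total = total + _masked_ce(head_j(ctx), tgts[:, j])
            count += len(node_rows)
    if bond_u:
        ctx = concat([h[np.asarray(bond_u)] + h[np.asarray(bond_v)],
                      image_embeddings[np.asarray(bond_imgs)]], axis=1)
        tgts = np.asarray(bond_tgts)
        for j, head_j in enumerate(head.edge_heads):
            total = total + _masked_ce(head_j(ctx), tgts[:, j])
            count += len(bond_u)
    return total * (1.0 / count)


# ---------------------------------------------------------------------------
# GIM


def sample_hard_negatives(similarities: np.ndarray,
                          rng: np.random.Generator | int) -> np.ndarray:
    """For each row i, draw one j != i with probability softmax(sim[i, j]).

    Higher-similarity (harder) negatives are drawn more often; the matched
    index is excluded from the support. Deterministic given the rng/seed.
    """
    sim = np.asarray(similarities, dtype=np.float64)
    k = sim.shape[0]
    if sim.shape != (k, k):
        raise ValueError("similarity matrix must be square")
    if k < 2:
        raise ValueError("need K >= 2 to sample negatives")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    logits = sim.copy()
    np.fill_diagonal(logits, -np.inf)
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    draws = rng.random(k)
    negatives = (draws[:, None] < cum).argmax(axis=1)
    return negatives


class FusionHead:
    """f_c: concat the two projected embeddings -> MLP -> softmax match prob."""

    def __init__(self, shared_dim: int, hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.mlp = MLP([2 * shared_dim, hidden, 2], rng)

    def match_probability(self, graph_proj: Tensor, image_proj: Tensor) -> Tensor:
        logits = self.mlp(concat([nn.as_tensor(graph_proj),
                                  nn.as_tensor(image_proj)], axis=1))
        # softmax over the two classes; index 1 = "matched"
        return (logits[:, 1] - logsumexp(logits, axis=1)).exp()

    def params(self, prefix: str = "gim.") -> dict[str, Tensor]:
        return self.mlp.params(prefix)


@dataclass
class MatchBatch:
    """Match probabilities with binary labels (1 = matched pair)."""

    probs: Tensor
    labels: np.ndarray

    def __post_init__(self):
        self.probs = nn.as_tensor(self.probs)
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.probs.shape != self.labels.shape:
            raise ValueError("probs/labels shape mismatch")
        if self.labels.sum() < 1 or (1 - self.labels).sum() < 1:
            raise ValueError("match batch needs at least one positive and one negative")


def gim_loss(batch: MatchBatch, eps: float = CLAMP_EPS) -> Tensor:
    """Binary cross-entropy averaged over the P + N candidate pairs."""
    p = batch.probs.clip(eps, 1.0 - eps)
    y = Tensor(batch.labels)
    ll = y * p.log() + (1.0 - y) * (1.0 - p).log()
    return -ll.mean()


# ---------------------------------------------------------------------------
# GM


class GMHeads:
    """Cross-modal VAE pair: q(z_I | z_G) with decoder z_G <- z_I, and the mirror.

    Each encoder outputs (mean, log-variance) of a diagonal Gaussian over the
    *other* modality's embedding space; each decoder reconstructs the source
    embedding from a reparameterized sample. Priors are standard normal.
    """

    def __init__(self, graph_dim: int, image_dim: int, hidden: int = 64,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.enc_g2i = MLP([graph_dim, hidden, 2 * image_dim], rng)
        self.dec_i2g = MLP([image_dim, hidden, graph_dim], rng)
        self.enc_i2g = MLP([image_dim, hidden, 2 * graph_dim], rng)
        self.dec_g2i = MLP([graph_dim, hidden, image_dim], rng)
        self.graph_dim, self.image_dim = graph_dim, image_dim

    def params(self, prefix: str = "gm.") -> dict[str, Tensor]:
        out = self.enc_g2i.params(f"{prefix}enc_g2i.")
        out.update(self.dec_i2g.params(f"{prefix}dec_i2g."))
        out.update(self.enc_i2g.params(f"{prefix}enc_i2g."))
        out.update(self.dec_g2i.params(f"{prefix}dec_g2i."))
        return out


def gaussian_kl(mu: Tensor, logvar: Tensor) -> Tensor:
    """Mean over batch of KL(N(mu, diag exp(logvar)) || N(0, I)), summed over dims."""
    per_dim = (mu * mu + logvar.exp() - 1.0 - logvar) * 0.5
    return per_dim.sum(axis=-1).mean()


def _vae_direction(source: Tensor, target_dim: int, enc: MLP, dec: MLP,
                   noise: np.ndarray, lambda_kl: float,
                   target: Tensor) -> Tensor:
    stats = enc(source)
    mu, logvar = stats[:, :target_dim], stats[:, target_dim:]
    sample = mu + logvar.clip(-10.0, 10.0).exp() ** 0.5 * Tensor(noise)
    recon = dec(sample)
    rec_err = ((recon - target) ** 2).sum(axis=-1).mean() * 0.5
    return rec_err + lambda_kl * gaussian_kl(mu, logvar)


def gm_loss(graph_embeddings: Tensor, image_embeddings: Tensor,
            heads: GMHeads, lambda_kl: float = 0.1,
            rng: np.random.Generator | None = None,
            noise: tuple[np.ndarray, np.ndarray] | None = None) -> Tensor:
    """Symmetric negative-ELBO over the two cross-modal directions.

    One reparameterized sample per direction; pass ``noise`` explicitly for
    deterministic evaluation (e.g. finite-difference gradient checks).
    """
    zg = nn.as_tensor(graph_embeddings)
    zi = nn.as_tensor(image_embeddings)
    if zg.shape[0] != zi.shape[0]:
        raise ValueError("batch sizes differ")
    if not (np.all(np.isfinite(zg.data)) and np.all(np.isfinite(zi.data))):
        raise FloatingPointError("non-finite embeddings passed to gm_loss")
    k = zg.shape[0]
    if noise is None:
        rng = rng if rng is not None else np.random.default_rng()
        noise = (rng.standard_normal((k, heads.image_dim)),
                 rng.standard_normal((k, heads.graph_dim)))
    # direction A: posterior over image latent given graph, reconstruct graph
    loss_a = _vae_direction(zg, heads.image_dim, heads.enc_g2i, heads.dec_i2g,
                            noise[0], lambda_kl, target=zg)
    # direction B: posterior over graph latent given image, reconstruct image
    loss_b = _vae_direction(zi, heads.graph_dim, heads.enc_i2g, heads.dec_g2i,
                            noise[1], lambda_kl, target=zi)
    return (loss_a + loss_b) * 0.5


# ---------------------------------------------------------------------------
# total


@dataclass
class LossReport:
    """Per-component scalars plus their weighted total."""

    gic: float = 0.0
    mgm: float = 0.0
    gim: float = 0.0
    gm: float = 0.0
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    total: float = field(init=False)

    def __post_init__(self):
        vals = (self.gic, self.mgm, self.gim, self.gm)
        if not all(np.isfinite(v) for v in vals):
            bad = [n for n, v in zip(("gic", "mgm", "gim", "gm"), vals)
                   if not np.isfinite(v)]
            raise FloatingPointError(f"non-finite loss component(s): {bad}")
        self.total = float(sum(w * v for w, v in zip(self.weights, vals)))

    def to_dict(self) -> dict:
        return {"gic": self.gic, "mgm": self.mgm, "gim": self.gim,
                "gm": self.gm, "total": self.total,
                "weights": list(self.weights)}


def total_loss(components: dict[str, Tensor | float],
               weights: dict[str, float] | None = None
               ) -> tuple[Tensor, LossReport]:
    """Weighted sum of the four objectives (default weights all 1)."""
    weights = dict(weights or {})
    w = [float(weights.get(k, 1.0)) for k in ("gic", "mgm", "gim", "gm")]
    if any(x < 0 for x in w):
        raise ValueError("loss weights must be nonnegative")
    terms = [components.get(k, 0.0) for k in ("gic", "mgm", "gim", "gm")]
    total = Tensor(0.0)
    for wi, term in zip(w, terms):
        total = total + nn.as_tensor(term) * wi
    report = LossReport(*(float(nn.as_tensor(t).data) for t in terms),
                        weights=tuple(w))
    return total, report
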