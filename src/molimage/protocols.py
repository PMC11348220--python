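"""Desk-scale evaluation protocols built on the synthetic generator.

These are the package's standard experiments:

* ``random_retrieval_baseline`` — uniform random ranking of one ground-truth
  item among ``neg`` negatives, the analytic floor every trained model is
  compared against (closed forms: E[MRR] = H_P/P, E[Hit@k] = k/P,
  E[AUC] = 1/2 for pool size P).
* ``zero_shot_random_baseline`` — uniform ranking of 20 actives + 100
  inactives, the floor of the zero-shot graph-retrieval protocol.
* ``signal_recovery`` — generate a paired dataset at signal strength alpha,
  pre-train on 300 molecules, and measure held-out retrieval with one
  ground-truth view per query among 100 sampled negatives (the 1:100
  protocol). At alpha = 0.9 the metrics should clear the random floor by a
  wide margin; at alpha = 0 they must stay inside its Monte-Carlo band.
* ``ablation_mrr`` — paired comparison of the contrastive objective alone
  vs contrastive + masked-graph-modeling across training seeds on one fixed
  dataset.

Problem sizes are the package defaults for CPU execution: 420 molecules
(300 train / 120 held-out queries), 4 views, 32 x 32 px, 30 epochs,
Adam at 3e-3 for these short schedules. Retrieval for these synthetic
experiments is evaluated in the projected common space, where the
contrastive objective actually aligns the modalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .retrieval import (RetrievalReport, random_baseline_closed_form,
                        random_baseline_monte_carlo, zero_shot_recall)
from .synth import SynthConfig, SynthDataset, generate_dataset
from .train import GraphImagePretrainer

__all__ = [
    "random_retrieval_baseline",
    "zero_shot_random_baseline",
    "random_metric_band",
    "signal_recovery",
    "ablation_mrr",
]

DESK_N_MOLECULES = 420
DESK_N_TRAIN = 300
DESK_VIEWS = 4
DESK_IMAGE_SIZE = 32
DESK_EPOCHS = 30
DESK_LR = 3e-3


def random_retrieval_baseline(n_queries: int = 100_000, neg_per_pos: int = 100,
                              seed: int = 0) -> dict:
    """Monte-Carlo random baseline for the 1:100 protocol plus closed forms."""
    pool = neg_per_pos + 1
    mc = random_baseline_monte_carlo(pool, n_queries, seed)
    return {"monte_carlo": mc.to_dict(),
            "closed_form": random_baseline_closed_form(pool),
            "pool_size": pool}


def zero_shot_random_baseline(n_trials: int = 5_000, n_pos: int = 20,
                              n_neg: int = 100, seed: int = 0,
                              Ns: tuple = (1, 3, 5, 10)) -> dict:
    """Mean Recall@N of uniformly random rankings of the active/inactive pool."""
    rng = np.random.default_rng(seed)
    sums = {n: 0.0 for n in Ns}
    for _ in range(n_trials):
        pool = rng.normal(size=(n_pos + n_neg, 4))
        rec = zero_shot_recall(rng.normal(size=4), pool[:n_pos], pool[n_pos:],
                               Ns)
        for n in Ns:
            sums[n] += rec[n]
    out = {f"recall@{n}": sums[n] / n_trials for n in Ns}
    out["expected"] = {f"recall@{n}": n / (n_pos + n_neg) for n in Ns}
    return out


def random_metric_band(n_queries: int, pool: int = 101, n_sims: int = 2_000,
                       seed: int = 123, level: float = 0.95) -> dict:
    """Monte-Carlo band of each random-ranking metric at the given query count."""
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    sims = {"mrr": [], "auc": [], "hit@1": [], "hit@5": [], "hit@10": []}
    for _ in range(n_sims):
        ranks = rng.integers(1, pool + 1, size=n_queries)
        sims["mrr"].append(np.mean(1.0 / ranks))
        sims["auc"].append(np.mean((pool - ranks) / (pool - 1)))
        for k in (1, 5, 10):
            sims[f"hit@{k}"].append(np.mean(ranks <= k))
    return {k: (float(np.quantile(v, lo_q)), float(np.quantile(v, hi_q)))
            for k, v in sims.items()}


def _desk_dataset(alpha: float, seed: int) -> SynthDataset:
    return generate_dataset(SynthConfig(
        n_molecules=DESK_N_MOLECULES, views_per_molecule=DESK_VIEWS,
        signal_strength=alpha, image_size=DESK_IMAGE_SIZE, seed=seed))


def _split(ds: SynthDataset, n_train: int = DESK_N_TRAIN):
    mols = sorted({g.molecule_id for g in ds.graphs})
    train_ids = set(mols[:n_train])
    tr_g = [g for g in ds.graphs if g.molecule_id in train_ids]
    tr_i = [im for im in ds.images if im.molecule_id in train_ids]
    te_g = [g for g in ds.graphs if g.molecule_id not in train_ids]
    # one view per held-out molecule: candidate pools are 1 positive + negatives
    te_i = [im for im in ds.images
            if im.molecule_id not in train_ids and im.view_id == 0]
    return tr_g, tr_i, te_g, te_i


def _fit(tr_g, tr_i, seed: int, loss_weights=(1.0, 1.0, 1.0, 1.0),
         epochs: int = DESK_EPOCHS) -> GraphImagePretrainer:
    est = GraphImagePretrainer(epochs=epochs, seed=seed, val_fraction=0.0,
                               learning_rate=DESK_LR,
                               loss_weights=loss_weights)
    est.fit(tr_g, tr_i)
    return est


def signal_recovery(alpha: float, data_seed: int = 11, train_seed: int = 0,
                    neg_per_pos: int = 100, eval_seed: int = 0) -> dict:
    """Pre-train at signal strength alpha; held-out 1:100 retrieval metrics."""
    ds = _desk_dataset(alpha, data_seed)
    tr_g, tr_i, te_g, te_i = _split(ds)
    est = _fit(tr_g, tr_i, train_seed)
    report = est.evaluate(te_g, te_i, neg_per_pos=neg_per_pos, seed=eval_seed,
                          projected=True)
    return {"alpha": alpha,
            "report": report.to_dict(),
            "random": random_baseline_closed_form(neg_per_pos + 1),
            "history": est.history_}


def ablation_mrr(n_seeds: int = 5, data_seed: int = 11,
                 neg_per_pos: int = 100, eval_seed: int = 0) -> dict:
    """Per-seed held-out MRR of GIC alone vs GIC + MGM on one fixed dataset."""
    ds = _desk_dataset(0.9, data_seed)
    tr_g, tr_i, te_g, te_i = _split(ds)
    gic, gic_mgm = [], []
    for seed in range(n_seeds):
        for name, weights, out in (("gic", (1, 0, 0, 0), gic),
                                   ("gic+mgm", (1, 1, 0, 0), gic_mgm)):
            est = _fit(tr_g, tr_i, seed, loss_weights=weights)
            rep = est.evaluate(te_g, te_i, neg_per_pos=neg_per_pos,
                               seed=eval_seed, projected=True)
            out.append(rep.mrr)
    return {"gic": gic, "gic_mgm": gic_mgm,
            "mean_gic": float(np.mean(gic)),
            "mean_gic_mgm": float(np.mean(gic_mgm)),
            "wins": int(sum(b >= a for a, b in zip(gic, gic_mgm)))}
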