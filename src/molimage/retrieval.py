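"""Embedding-space ranking and retrieval statistics.

Retrieval is a ranking problem: given a query embedding (a molecule, say),
candidates (its images plus sampled negatives) are ordered by distance and
the rank of the ground truth summarised over queries as

* MRR   — mean of 1 / best rank,
* Hit@k — fraction of queries whose best rank is <= k,
* AUC   — mean normalized rank (pool - rank) / (pool - 1), i.e. the
  Mann-Whitney probability that the positive outranks a random negative;
  0.5 under uniform random ranking.

The zero-shot protocol ranks a pool of known-active and inactive molecules
against a query image embedding and reports Recall@N, the fraction of all
actives appearing in the top N.

Closed forms for uniform random ranking (used as analytic baselines): with
one positive in a pool of size P, E[MRR] = H_P / P (harmonic number),
E[Hit@k] = k / P, E[AUC] = 1/2; with ``p`` positives in a pool of size P,
E[Recall@N] = N / P.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RankingTask",
    "RetrievalReport",
    "rank_candidates",
    "retrieval_metrics",
    "evaluate_pairs",
    "zero_shot_recall",
    "random_baseline_closed_form",
    "random_baseline_monte_carlo",
]


@dataclass
class RankingTask:
    query: np.ndarray
    candidates: np.ndarray  # (n, d)
    candidate_ids: Sequence[str]
    ground_truth_ids: frozenset = frozenset()
    distance: str = "l2"  # or "cosine"

    def __post_init__(self):
        self.query = np.asarray(self.query, dtype=np.float64)
        self.candidates = np.atleast_2d(np.asarray(self.candidates,
                                                   dtype=np.float64))
        self.candidate_ids = list(self.candidate_ids)
        if self.candidates.shape[0] < 1:
            raise ValueError("need at least one candidate")
        if self.candidates.shape[1] != self.query.shape[-1]:
            raise ValueError("query/candidate dimension mismatch")
        if len(self.candidate_ids) != self.candidates.shape[0]:
            raise ValueError("candidate ids/embeddings length mismatch")


@dataclass
class RetrievalReport:
    best_ranks: np.ndarray
    pool_sizes: np.ndarray
    mrr: float
    auc: float
    hit_at: dict[int, float]
    recall_at: dict[int, float] = field(default_factory=dict)
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_queries(self) -> int:
        return len(self.best_ranks)

    def to_dict(self) -> dict:
        return {
            "n_queries": self.n_queries,
            "mrr": self.mrr,
            "auc": self.auc,
            **{f"hit@{k}": v for k, v in sorted(self.hit_at.items())},
            **{f"recall@{n}": v for n, v in sorted(self.recall_at.items())},
        }


def _distances(query: np.ndarray, candidates: np.ndarray, kind: str
               ) -> np.ndarray:
    if kind == "l2":
        return np.linalg.norm(candidates - query, axis=1)
    if kind == "cosine":
        qn = query / (np.linalg.norm(query) + 1e-12)
        cn = candidates / (np.linalg.norm(candidates, axis=1, keepdims=True)
                           + 1e-12)
        return 1.0 - cn @ qn
    raise ValueError(f"unknown distance {kind!r}")


def rank_candidates(task: RankingTask) -> list[tuple[str, int]]:
    """Candidates in ascending distance order with 1-based ranks.

    Ties are broken by lexicographic candidate id, so rankings are
    deterministic regardless of input order.
    """
    dist = _distances(task.query, task.candidates, task.distance)
    order = sorted(range(len(dist)),
                   key=lambda i: (dist[i], str(task.candidate_ids[i])))
    return [(task.candidate_ids[i], r + 1) for r, i in enumerate(order)]


def best_rank(task: RankingTask) -> int:
    """1-based rank of the best-ranked ground-truth candidate."""
    if not task.ground_truth_ids:
        raise ValueError("task has no ground-truth ids")
    ranked = rank_candidates(task)
    for cid, r in ranked:
        if cid in task.ground_truth_ids:
            return r
    raise ValueError("ground-truth ids not among candidates")


def retrieval_metrics(best_ranks: Sequence[int], pool_sizes: Sequence[int],
                      ks: Sequence[int] = (1, 5, 10)) -> RetrievalReport:
    """Aggregate per-query best ranks into MRR / AUC / Hit@k."""
    ranks = np.asarray(best_ranks, dtype=np.int64)
    pools = np.asarray(pool_sizes, dtype=np.int64)
    if ranks.shape != pools.shape or ranks.ndim != 1 or len(ranks) == 0:
        raise ValueError("ranks and pool sizes must be matching 1-D arrays")
    if np.any(ranks < 1) or np.any(ranks > pools):
        raise ValueError("ranks must satisfy 1 <= rank <= pool size")
    mrr = float(np.mean(1.0 / ranks))
    # Mann-Whitney with one positive: fraction of negatives ranked below it
    denom = np.maximum(pools - 1, 1)
    auc = float(np.mean((pools - ranks) / denom))
    hit = {int(k): float(np.mean(ranks <= k)) for k in ks}
    return RetrievalReport(ranks, pools, mrr, auc, hit)


def evaluate_pairs(graph_embeddings: dict[str, np.ndarray],
                   image_embeddings: list[tuple[str, np.ndarray]],
                   direction: str = "image_retrieval",
                   neg_per_pos: int = 100,
                   seed: int = 0,
                   ks: Sequence[int] = (1, 5, 10),
                   distance: str = "l2") -> RetrievalReport:
    """Paired-retrieval protocol: per query, rank ground truth among negatives.

    ``image_retrieval`` queries each molecule's graph embedding against a
    pool of all its own images (ground truth — best rank counts) plus
    ``neg_per_pos`` images of other molecules, sampled with a per-query seed.
    ``graph_retrieval`` queries each image against its molecule's graph plus
    negative graphs.
    """
    if direction not in ("image_retrieval", "graph_retrieval"):
        raise ValueError(f"unknown direction {direction!r}")
    # canonical candidate order (molecule id, then embedding content) so the
    # seeded negative draw is invariant to how the caller ordered the images
    mol_arr = np.array([m for m, _ in image_embeddings])
    emb_arr = np.stack([e for _, e in image_embeddings])
    order = np.lexsort(tuple(emb_arr.T[::-1]) + (mol_arr,))
    image_embeddings = [image_embeddings[i] for i in order]
    ranks, pools = [], []
    if direction == "image_retrieval":
        mol_of = mol_arr[order]
        embs = emb_arr[order]
        for qi, (mol, zg) in enumerate(sorted(graph_embeddings.items())):
            pos_idx = np.flatnonzero(mol_of == mol)
            neg_idx = np.flatnonzero(mol_of != mol)
            if len(pos_idx) == 0:
                raise ValueError(f"no ground-truth images for {mol!r}")
            if neg_per_pos > len(neg_idx):
                raise ValueError("neg_per_pos exceeds available negatives")
            rng = np.random.default_rng([seed, qi])  # per-query negative pool
            chosen = rng.choice(neg_idx, size=neg_per_pos, replace=False)
            pool_idx = np.concatenate([pos_idx, chosen])
            ids = [f"pos{j}" if j < len(pos_idx) else f"zneg{j}"
                   for j in range(len(pool_idx))]
            task = RankingTask(zg, embs[pool_idx], ids,
                               frozenset(ids[:len(pos_idx)]), distance)
            ranks.append(best_rank(task))
            pools.append(len(pool_idx))
    else:
        mols = sorted(graph_embeddings)
        gembs = np.stack([graph_embeddings[m] for m in mols])
        mol_pos = {m: i for i, m in enumerate(mols)}
        for qi, (mol, zi) in enumerate(image_embeddings):
            if mol not in mol_pos:
                raise ValueError(f"image of unknown molecule {mol!r}")
            neg_idx = np.array([i for m, i in mol_pos.items() if m != mol])
            if neg_per_pos > len(neg_idx):
                raise ValueError("neg_per_pos exceeds available negatives")
            rng = np.random.default_rng([seed, qi])
            chosen = rng.choice(neg_idx, size=neg_per_pos, replace=False)
            pool_idx = np.concatenate([[mol_pos[mol]], chosen])
            ids = [f"pos{j}" if j < 1 else f"zneg{j}"
                   for j in range(len(pool_idx))]
            task = RankingTask(zi, gembs[pool_idx], ids, frozenset([ids[0]]),
                               distance)
            ranks.append(best_rank(task))
            pools.append(len(pool_idx))
    return retrieval_metrics(ranks, pools, ks)


def zero_shot_recall(query_embedding: np.ndarray,
                     positive_embeddings: np.ndarray,
                     negative_embeddings: np.ndarray,
                     Ns: Sequence[int] = (1, 3, 5, 10),
                     distance: str = "l2") -> dict[int, float]:
    """Recall@N of known actives in a ranked active+inactive pool.

    Recall@N = (# positives in top N) / (total positives).
    """
    pos = np.atleast_2d(positive_embeddings)
    neg = np.atleast_2d(negative_embeddings)
    n_pos, n_neg = pos.shape[0], neg.shape[0]
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one positive and one negative")
    pool = np.concatenate([pos, neg])
    if max(Ns) > pool.shape[0]:
        raise ValueError("N exceeds pool size")
    ids = [f"p{i:06d}" for i in range(n_pos)] + \
          [f"q{i:06d}" for i in range(n_neg)]
    ranked = rank_candidates(RankingTask(query_embedding, pool, ids,
                                         frozenset(ids[:n_pos]), distance))
    is_pos = np.array([cid.startswith("p") for cid, _ in ranked])
    return {int(N): float(is_pos[:N].sum() / n_pos) for N in Ns}


# ---------------------------------------------------------------------------
# analytic random baselines


def random_baseline_closed_form(pool_size: int, ks: Sequence[int] = (1, 5, 10)
                                ) -> dict[str, float]:
    """Expected metrics under uniform random ranking, one positive in the pool."""
    p = int(pool_size)
    harmonic = float(np.sum(1.0 / np.arange(1, p + 1)))
    out = {"mrr": harmonic / p, "auc": 0.5}
    out.update({f"hit@{k}": min(k, p) / p for k in ks})
    return out


def random_baseline_monte_carlo(pool_size: int, n_queries: int, seed: int,
                                ks: Sequence[int] = (1, 5, 10)
                                ) -> RetrievalReport:
    """Uniform random best-ranks pushed through :func:`retrieval_metrics`."""
    rng = np.random.default_rng(seed)
    ranks = rng.integers(1, pool_size + 1, size=n_queries)
    return retrieval_metrics(ranks, np.full(n_queries, pool_size), ks)
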