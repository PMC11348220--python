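"""Attributed molecular graphs: data model, JSON-lines I/O, and masking.

A molecule is an attributed graph G = (V, E): an integer node-attribute
matrix (atom-type index first, optional extra categorical attributes after)
and an integer edge-attribute matrix (bond-type index first). Undirected
bonds are stored as two mutually inverse directed arcs so that message
passing is direction-symmetric.

The masking transform supports masked-attribute pre-training: nodes and
bonds are independently selected at a configurable rate and their attributes
replaced by a reserved mask token; the :class:`MaskSpec` records the true
targets so the original graph can be restored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MolecularGraph",
    "AttributeVocabulary",
    "MaskSpec",
    "read_graphs",
    "write_graphs",
    "graph_from_smiles",
    "mask_graph",
    "unmask_graph",
]

#: atom-type vocabulary spans the periodic table by atomic number (1..118,
#: plus index 0 reserved for "unknown"); bond types: single/double/triple/aromatic
DEFAULT_NUM_ATOM_TYPES = 119
DEFAULT_NUM_BOND_TYPES = 4


@dataclass(frozen=True)
class AttributeVocabulary:
    """Category counts per node/edge attribute plus the reserved mask token.

    ``mask_token_index`` for attribute ``j`` equals its vocabulary size, i.e.
    one past the last real category, so it never collides with real data.
    """

    node_vocab_sizes: tuple[int, ...] = (DEFAULT_NUM_ATOM_TYPES,)
    edge_vocab_sizes: tuple[int, ...] = (DEFAULT_NUM_BOND_TYPES,)

    def __post_init__(self):
        for sizes in (self.node_vocab_sizes, self.edge_vocab_sizes):
            if any(s < 2 for s in sizes):
                raise ValueError(f"vocabulary sizes must be >= 2, got {sizes}")

    @property
    def node_mask_tokens(self) -> tuple[int, ...]:
        return tuple(self.node_vocab_sizes)

    @property
    def edge_mask_tokens(self) -> tuple[int, ...]:
        return tuple(self.edge_vocab_sizes)

    def embedding_sizes(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """Vocab sizes including the mask token (what an embedding table needs)."""
        return (tuple(s + 1 for s in self.node_vocab_sizes),
                tuple(s + 1 for s in self.edge_vocab_sizes))


@dataclass
class MolecularGraph:
    """Attributed graph with n nodes and m directed arcs (2 per bond)."""

    node_attrs: np.ndarray  # (n, d_n) int
    edge_index: np.ndarray  # (m, 2) int, directed arcs
    edge_attrs: np.ndarray  # (m, d_e) int
    molecule_id: str = ""

    def __post_init__(self):
        self.node_attrs = np.atleast_2d(np.asarray(self.node_attrs, dtype=np.int64))
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64).reshape(-1, 2)
        self.edge_attrs = np.asarray(self.edge_attrs, dtype=np.int64)
        if self.edge_attrs.size == 0:
            self.edge_attrs = self.edge_attrs.reshape(0, 1)
        self.edge_attrs = np.atleast_2d(self.edge_attrs)
        self.validate()

    @property
    def num_nodes(self) -> int:
        return self.node_attrs.shape[0]

    @property
    def num_arcs(self) -> int:
        return self.edge_index.shape[0]

    @property
    def num_bonds(self) -> int:
        return self.num_arcs // 2

    def validate(self) -> None:
        n = self.num_nodes
        if n < 1:
            raise ValueError("a molecular graph needs at least one node")
        if self.num_arcs != self.edge_attrs.shape[0]:
            raise ValueError("edge_index and edge_attrs row counts differ")
        if self.num_arcs:
            if self.edge_index.min() < 0 or self.edge_index.max() >= n:
                raise ValueError(
                    f"edge endpoint out of range for {n} nodes "
                    f"(molecule {self.molecule_id!r})")
            if self.num_arcs % 2:
                raise ValueError("directed arcs must come in inverse pairs")

    def bond_arc_pairs(self) -> np.ndarray:
        """(num_bonds, 2) arc indices such that pair rows are mutual inverses.

        Arcs are stored as consecutive (u,v),(v,u) pairs by every constructor
        in this package; this verifies and returns that pairing.
        """
        idx = np.arange(self.num_arcs).reshape(-1, 2)
        fwd, rev = self.edge_index[idx[:, 0]], self.edge_index[idx[:, 1]]
        if not (np.array_equal(fwd, rev[:, ::-1])
                and np.array_equal(self.edge_attrs[idx[:, 0]],
                                   self.edge_attrs[idx[:, 1]])):
            raise ValueError("arcs are not stored as consecutive inverse pairs")
        return idx

    def copy(self) -> "MolecularGraph":
        return MolecularGraph(self.node_attrs.copy(), self.edge_index.copy(),
                              self.edge_attrs.copy(), self.molecule_id)

    def check_vocab(self, vocab: AttributeVocabulary,
                    allow_mask: bool = False) -> None:
        node_max, edge_max = vocab.embedding_sizes() if allow_mask else (
            vocab.node_vocab_sizes, vocab.edge_vocab_sizes)
        for j, cap in enumerate(node_max):
            col = self.node_attrs[:, j]
            if col.min(initial=0) < 0 or col.max(initial=0) >= cap:
                raise ValueError(
                    f"node attribute {j} outside vocabulary of size {cap}")
        if self.num_arcs:
            for j, cap in enumerate(edge_max):
                col = self.edge_attrs[:, j]
                if col.min() < 0 or col.max() >= cap:
                    raise ValueError(
                        f"edge attribute {j} outside vocabulary of size {cap}")


@dataclass
class MaskSpec:
    """Which nodes/bonds were masked and what the true attributes were."""

    masked_node_indices: np.ndarray
    masked_edge_indices: np.ndarray  # arc indices; both arcs of a bond present
    node_targets: np.ndarray  # (k_n, d_n)
    edge_targets: np.ndarray  # (k_e, d_e)
    mask_rate: float = 0.15
    seed: int = 0

    def __post_init__(self):
        self.masked_node_indices = np.asarray(self.masked_node_indices, dtype=np.int64)
        self.masked_edge_indices = np.asarray(self.masked_edge_indices, dtype=np.int64)
        self.node_targets = np.atleast_2d(np.asarray(self.node_targets, dtype=np.int64))
        self.edge_targets = np.atleast_2d(np.asarray(self.edge_targets, dtype=np.int64))
        if len(self.masked_node_indices) != len(set(self.masked_node_indices.tolist())):
            raise ValueError("masked node indices must be unique")
        if self.node_targets.size and self.node_targets.shape[0] != len(
                self.masked_node_indices):
            raise ValueError("node targets / indices length mismatch")

    @property
    def is_empty(self) -> bool:
        return len(self.masked_node_indices) == 0 and len(self.masked_edge_indices) == 0


# ---------------------------------------------------------------------------
# JSON-lines I/O
#
# One object per molecule: {"id": str, "nodes": [[attr, ...], ...],
# "edges": [[u, v, attr, ...], ...]} with 0-based node indices and one entry
# per undirected bond (arcs are doubled on read).


class GraphParseError(ValueError):
    pass


def _graph_from_record(rec: dict, default_id: str) -> MolecularGraph:
    nodes = rec.get("nodes")
    if not nodes:
        raise GraphParseError("record has no nodes")
    node_attrs = np.asarray(nodes, dtype=np.int64)
    edges = rec.get("edges", [])
    n_attr_cols = None
    arc_index, arc_attrs = [], []
    for e in edges:
        u, v, *attrs = e
        if n_attr_cols is None:
            n_attr_cols = len(attrs)
        arc_index += [[u, v], [v, u]]
        arc_attrs += [attrs, attrs]
    if not edges:
        edge_index = np.zeros((0, 2), dtype=np.int64)
        edge_attrs = np.zeros((0, 1), dtype=np.int64)
    else:
        edge_index = np.asarray(arc_index, dtype=np.int64)
        edge_attrs = np.asarray(arc_attrs, dtype=np.int64)
        if edge_attrs.ndim == 1:
            edge_attrs = edge_attrs[:, None]
    return MolecularGraph(node_attrs, edge_index, edge_attrs,
                          str(rec.get("id", default_id)))


def read_graphs(path: str | Path, format: str = "jsonl") -> list[MolecularGraph]:
    """Read molecular graphs from a JSON-lines file or a SMILES list.

    ``format='smiles'`` expects one SMILES per line (optionally followed by
    whitespace and an id) and requires rdkit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    graphs: list[MolecularGraph] = []
    if format == "jsonl":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                    graphs.append(_graph_from_record(rec, default_id=str(lineno)))
                except (json.JSONDecodeError, TypeError, KeyError) as exc:
                    raise GraphParseError(
                        f"{path}:{lineno}: malformed graph record: {exc}") from exc
                except ValueError as exc:
                    raise GraphParseError(f"{path}:{lineno}: {exc}") from exc
    elif format == "smiles":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                mol_id = parts[1] if len(parts) > 1 else str(lineno)
                try:
                    graphs.append(graph_from_smiles(parts[0], molecule_id=mol_id))
                except ValueError as exc:
                    raise GraphParseError(f"{path}:{lineno}: {exc}") from exc
    else:
        raise ValueError(f"unknown graph format {format!r}")
    return graphs


def write_graphs(graphs: Iterable[MolecularGraph], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for g in graphs:
            pairs = g.bond_arc_pairs()[:, 0]
            edges = [[int(g.edge_index[a, 0]), int(g.edge_index[a, 1]),
                      *map(int, g.edge_attrs[a])] for a in pairs]
            rec = {"id": g.molecule_id,
                   "nodes": g.node_attrs.tolist(),
                   "edges": edges}
            fh.write(json.dumps(rec, separators=(",", ":")) + "\n")


_BOND_TYPE_INDEX = {"SINGLE": 0, "DOUBLE": 1, "TRIPLE": 2, "AROMATIC": 3}


def graph_from_smiles(smiles: str, molecule_id: str = "") -> MolecularGraph:
    """Build a graph from SMILES (atom-type = atomic number, bond-type 0..3)."""
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "SMILES ingestion requires rdkit; install the 'chem' extra") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"rdkit could not parse SMILES {smiles!r}")
    node_attrs = np.array([[a.GetAtomicNum()] for a in mol.GetAtoms()],
                          dtype=np.int64)
    arc_index, arc_attrs = [], []
    for b in mol.GetBonds():
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        t = _BOND_TYPE_INDEX.get(str(b.GetBondType()), 0)
        arc_index += [[u, v], [v, u]]
        arc_attrs += [[t], [t]]
    if not arc_index:
        edge_index = np.zeros((0, 2), dtype=np.int64)
        edge_attrs = np.zeros((0, 1), dtype=np.int64)
    else:
        edge_index = np.asarray(arc_index, dtype=np.int64)
        edge_attrs = np.asarray(arc_attrs, dtype=np.int64)
    return MolecularGraph(node_attrs, edge_index, edge_attrs,
                          molecule_id or smiles)


# ---------------------------------------------------------------------------
# masking


def mask_graph(graph: MolecularGraph, rate: float, vocab: AttributeVocabulary,
               seed: int) -> tuple[MolecularGraph, MaskSpec]:
    """Independently mask nodes and bonds at probability ``rate``.

    Each node, and each undirected bond (both of its arcs together), is
    selected with probability ``rate`` under ``seed``; selected attributes are
    replaced by the vocabulary's reserved mask token. The input is untouched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mask rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    out = graph.copy()

    node_sel = np.flatnonzero(rng.random(graph.num_nodes) < rate)
    bond_pairs = graph.bond_arc_pairs()
    bond_sel = np.flatnonzero(rng.random(graph.num_bonds) < rate) \
        if graph.num_bonds else np.zeros(0, dtype=np.int64)
    arc_sel = bond_pairs[bond_sel].ravel() if len(bond_sel) else np.zeros(
        0, dtype=np.int64)

    d_n = graph.node_attrs.shape[1]
    d_e = graph.edge_attrs.shape[1]
    node_targets = graph.node_attrs[node_sel].copy()
    edge_targets = graph.edge_attrs[arc_sel].copy()
    out.node_attrs[node_sel] = np.asarray(vocab.node_mask_tokens[:d_n])
    if len(arc_sel):
        out.edge_attrs[arc_sel] = np.asarray(vocab.edge_mask_tokens[:d_e])
    spec = MaskSpec(node_sel, arc_sel,
                    node_targets.reshape(-1, d_n),
                    edge_targets.reshape(-1, d_e),
                    mask_rate=rate, seed=seed)
    return out, spec


def unmask_graph(masked: MolecularGraph, spec: MaskSpec) -> MolecularGraph:
    """Substitute the recorded true targets back; inverse of :func:`mask_graph`."""
    out = masked.copy()
    if len(spec.masked_node_indices):
        out.node_attrs[spec.masked_node_indices] = spec.node_targets
    if len(spec.masked_edge_indices):
        out.edge_attrs[spec.masked_edge_indices] = spec.edge_targets
    return out
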