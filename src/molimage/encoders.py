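"""Unimodal encoders and the common-space projection heads.

Graph side: a Graph Isomorphism Network (GIN) with edge features. Node
states start as embedded atom attributes; each of L layers aggregates
messages h_u + embed(edge attrs) over in-arcs by summation and applies a
two-layer MLP update. The graph embedding z_G is the sum (optionally mean)
of final node states — sum aggregation keeps the encoder as discriminative
as the 1-WL test and exactly invariant to node relabeling.

Image side: a small from-scratch strided convolutional stack with global
average pooling and an affine output. The encoder is a contract — anything
mapping a C x H x W stack to a fixed-dimension vector can be plugged in —
and the default deliberately avoids pretrained weights so the package is
self-contained and CPU-friendly.

Two affine projection heads (one per modality) map the encoder outputs into
a shared space where contrastive similarity is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .graphs import AttributeVocabulary, MolecularGraph
from .images import CellImage
from .nn import Linear, MLP, Tensor, canonical_segment_sum, init_uniform

__all__ = [
    "GINConfig",
    "ImageEncoderConfig",
    "GraphBatch",
    "GraphEncoder",
    "ImageEncoder",
    "ProjectionHeads",
    "gin_forward",
    "readout",
    "encode_image",
    "project",
]


@dataclass(frozen=True)
class GINConfig:
    num_layers: int = 5
    hidden_dim: int = 300
    vocab: AttributeVocabulary = field(default_factory=AttributeVocabulary)
    readout: str = "sum"  # or "mean"
    seed: int = 0

    def __post_init__(self):
        if self.num_layers < 0:
            raise ValueError("num_layers must be >= 0")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if self.readout not in ("sum", "mean"):
            raise ValueError(f"unknown readout {self.readout!r}")


@dataclass(frozen=True)
class ImageEncoderConfig:
    in_channels: int = 5
    embed_dim: int = 300
    conv_widths: tuple[int, ...] = (8, 16, 32)
    kernel: int = 3
    stride: int = 2
    image_size: int = 128
    seed: int = 0


class GraphBatch:
    """Several graphs concatenated into one disjoint union.

    Node/arc arrays are stacked with node indices offset per graph;
    ``node_graph_ids`` maps each node back to its graph so readout is a
    segment sum.
    """

    def __init__(self, graphs: Sequence[MolecularGraph]):
        if not graphs:
            raise ValueError("empty graph batch")
        offsets = np.cumsum([0] + [g.num_nodes for g in graphs[:-1]])
        self.node_attrs = np.concatenate([g.node_attrs for g in graphs])
        self.edge_index = np.concatenate(
            [g.edge_index + off for g, off in zip(graphs, offsets)])
        self.edge_attrs = np.concatenate([g.edge_attrs for g in graphs])
        self.node_graph_ids = np.concatenate(
            [np.full(g.num_nodes, i) for i, g in enumerate(graphs)])
        self.node_offsets = offsets
        self.num_graphs = len(graphs)
        self.num_nodes = self.node_attrs.shape[0]


class GraphEncoder:
    """GIN with per-attribute embedding tables and edge-featured messages."""

    def __init__(self, config: GINConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        node_sizes, edge_sizes = config.vocab.embedding_sizes()
        d = config.hidden_dim
        self.node_tables = [init_uniform(rng, (s, d), 1) for s in node_sizes]
        self.layers = []
        for _ in range(config.num_layers):
            edge_tables = [init_uniform(rng, (s, d), 1) for s in edge_sizes]
            update = MLP([d, 2 * d, d], rng)
            self.layers.append((edge_tables, update))

    def embed_nodes(self, batch: GraphBatch) -> Tensor:
        h = self.node_tables[0][batch.node_attrs[:, 0]]
        for j in range(1, batch.node_attrs.shape[1]):
            h = h + self.node_tables[j][batch.node_attrs[:, j]]
        return h

    def node_embeddings(self, batch: GraphBatch) -> Tensor:
        """Run all message-passing layers; (total_nodes, hidden_dim)."""
        h = self.embed_nodes(batch)
        src, dst = batch.edge_index[:, 0], batch.edge_index[:, 1]
        for edge_tables, update in self.layers:
            if len(src):
                e = edge_tables[0][batch.edge_attrs[:, 0]]
                for j in range(1, batch.edge_attrs.shape[1]):
                    e = e + edge_tables[j][batch.edge_attrs[:, j]]
                msg = h[src] + e
                # value-canonical order: exact equivariance under relabeling
                agg = canonical_segment_sum(msg, dst, batch.num_nodes)
            else:
                agg = Tensor(np.zeros_like(h.data))
            h = update(h + agg)
        return h

    def graph_embeddings(self, batch: GraphBatch) -> Tensor:
        h = self.node_embeddings(batch)
        z = canonical_segment_sum(h, batch.node_graph_ids, batch.num_graphs)
        if self.config.readout == "mean":
            counts = np.bincount(batch.node_graph_ids,
                                 minlength=batch.num_graphs).astype(float)
            z = z * Tensor(1.0 / counts[:, None])
        return z

    def encode(self, graphs: Sequence[MolecularGraph]) -> Tensor:
        return self.graph_embeddings(GraphBatch(graphs))

    def params(self, prefix: str = "gin.") -> dict[str, Tensor]:
        out = {f"{prefix}node_table{j}": t for j, t in enumerate(self.node_tables)}
        for i, (edge_tables, update) in enumerate(self.layers):
            for j, t in enumerate(edge_tables):
                out[f"{prefix}layer{i}.edge_table{j}"] = t
            out.update(update.params(f"{prefix}layer{i}.mlp."))
        return out


class ImageEncoder:
    """Strided conv stack -> ReLU -> global average pool -> affine output.

    The number of conv layers is chosen at construction so every layer sees a
    spatial extent of at least the kernel size for the configured image size.
    """

    def __init__(self, config: ImageEncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k, s = config.kernel, config.stride
        self.convs: list[tuple[Tensor, Tensor]] = []
        c, size = config.in_channels, config.image_size
        for width in config.conv_widths:
            if size < k:
                break
            w = init_uniform(rng, (width, c, k, k), c * k * k)
            b = init_uniform(rng, (width,), c * k * k)
            self.convs.append((w, b))
            c, size = width, (size - k) // s + 1
        if not self.convs:
            raise ValueError(
                f"image_size {config.image_size} too small for kernel {k}")
        self.out = Linear(c, config.embed_dim, rng)

    def forward(self, pixels: np.ndarray | Tensor) -> Tensor:
        """pixels: (N, C, H, W) -> (N, embed_dim)."""
        x = nn.as_tensor(pixels)
        if x.ndim == 3:
            x = x.reshape((1,) + x.shape)
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} channels, got {x.shape[1]}")
        for w, b in self.convs:
            x = nn.conv2d(x, w, b, stride=self.config.stride).relu()
        x = x.mean(axis=3).mean(axis=2)  # global average pool
        return self.out(x)

    def encode(self, images: Sequence[CellImage]) -> Tensor:
        stack = np.stack([im.pixels for im in images])
        return self.forward(stack)

    def params(self, prefix: str = "img.") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for i, (w, b) in enumerate(self.convs):
            out[f"{prefix}conv{i}.weight"] = w
            out[f"{prefix}conv{i}.bias"] = b
        out.update(self.out.params(f"{prefix}out."))
        return out


class ProjectionHeads:
    """Affine maps f_v (graph) and f_w (image) into the shared space."""

    def __init__(self, graph_dim: int, image_dim: int, shared_dim: int,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.graph_head = Linear(graph_dim, shared_dim, rng)
        self.image_head = Linear(image_dim, shared_dim, rng)
        self.shared_dim = shared_dim

    def project_graph(self, z: Tensor | np.ndarray) -> Tensor:
        z = nn.as_tensor(z)
        if z.shape[-1] != self.graph_head.weight.shape[0]:
            raise ValueError("graph embedding dimension mismatch")
        return self.graph_head(z)

    def project_image(self, z: Tensor | np.ndarray) -> Tensor:
        z = nn.as_tensor(z)
        if z.shape[-1] != self.image_head.weight.shape[0]:
            raise ValueError("image embedding dimension mismatch")
        return self.image_head(z)

    def params(self, prefix: str = "proj.") -> dict[str, Tensor]:
        out = self.graph_head.params(f"{prefix}graph.")
        out.update(self.image_head.params(f"{prefix}image."))
        return out


# -- thin functional wrappers over the classes ------------------------------

def gin_forward(graph: MolecularGraph, encoder: GraphEncoder) -> np.ndarray:
    """Per-node representations after all GIN layers; (n, hidden_dim)."""
    graph.check_vocab(encoder.config.vocab, allow_mask=True)
    return encoder.node_embeddings(GraphBatch([graph])).data


def readout(node_embeddings: np.ndarray, mode: str = "sum") -> np.ndarray:
    node_embeddings = np.asarray(node_embeddings)
    if node_embeddings.ndim != 2 or node_embeddings.shape[0] < 1:
        raise ValueError("readout needs a nonempty (n, d) matrix")
    # canonical row order makes the float sum permutation-invariant exactly
    order = np.lexsort(tuple(node_embeddings.T[::-1]))
    z = node_embeddings[order].sum(axis=0)
    return z / node_embeddings.shape[0] if mode == "mean" else z


def encode_image(image: CellImage, encoder: ImageEncoder) -> np.ndarray:
    return encoder.encode([image]).data[0]


def project(z: np.ndarray, heads: ProjectionHeads, modality: str) -> np.ndarray:
    if modality == "graph":
        return heads.project_graph(z).data
    if modality == "image":
        return heads.project_image(z).data
    raise ValueError(f"unknown modality {modality!r}")
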