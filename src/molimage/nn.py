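"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains small encoders (a GIN over molecular graphs, a strided
convolutional stack over 5-channel cell images) and several loss heads on a
single CPU. This module provides the tensor/op machinery those components
share: a :class:`Tensor` wrapping a float64 ndarray, a handful of primitive
ops with hand-written vector-Jacobian products, seeded parameter
initialisation, and an Adam optimizer.

Everything runs in float64. That keeps finite-difference gradient checks
tight (relative error < 1e-4 is routinely achievable) and determinism exact;
at the problem sizes this package targets the speed cost is irrelevant.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "segment_sum",
    "canonical_segment_sum",
    "conv2d",
    "logsumexp",
    "softmax",
    "Linear",
    "MLP",
    "Adam",
    "init_uniform",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # leading added axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph: float64 data plus a backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor._make(data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data**(p - 1))

        return Tensor._make(data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accumulate(self.data.swapaxes(-1, -2) @ g)

        return Tensor._make(data, (self, other), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * data)

        return Tensor._make(data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self):
        data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - data**2))

        return Tensor._make(data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(data, (self,), backward)

    def sigmoid(self):
        data = 0.5 * (np.tanh(0.5 * self.data) + 1.0)  # stable logistic

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * data * (1.0 - data))

        return Tensor._make(data, (self,), backward)

    def clip(self, lo: float, hi: float):
        data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(data, (self,), backward)

    # -- reductions / shape -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        return Tensor._make(data, (self,), backward)

    def transpose(self, *axes):
        axes = axes or None
        data = self.data.transpose(axes) if axes else self.data.T
        inv = np.argsort(axes) if axes else None

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv) if inv is not None else g.T)

        return Tensor._make(data, (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor._make(data, (self,), backward)

    # -- backprop -----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(part)

    return Tensor._make(data, tuple(tensors), backward)


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets (scatter-add).

    The workhorse of message passing: aggregating per-edge messages onto
    target nodes and per-node vectors onto graphs.
    """
    x = as_tensor(x)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    data = np.zeros((num_segments,) + x.shape[1:], dtype=np.float64)
    np.add.at(data, segment_ids, x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g[segment_ids])

    return Tensor._make(data, (x,), backward)


def canonical_segment_sum(x: Tensor, segment_ids: np.ndarray,
                          num_segments: int) -> Tensor:
    """Segment sum with a value-canonical accumulation order.

    Rows are lexicographically sorted within each segment before the
    scatter-add, so the floating-point result is bit-identical for any
    permutation of the input rows — what makes sum-readout graph encoders
    *exactly* invariant to node relabeling rather than invariant up to
    round-off.
    """
    x = as_tensor(x)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    keys = tuple(x.data.T[::-1]) + (segment_ids,)  # segment is primary key
    order = np.lexsort(keys)
    return segment_sum(x[order], segment_ids[order], num_segments)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    # max is treated as a constant shift: its gradient contribution cancels
    m = np.max(x.data, axis=axis, keepdims=True)
    shifted = x - Tensor(m)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    return out if keepdims else out.reshape(np.squeeze(out.data, axis=axis).shape)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return (x - logsumexp(x, axis=axis, keepdims=True)).exp()


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    """Valid (no padding) strided 2-D convolution.

    x: (N, C, H, W); w: (F, C, k, k); b: (F,) or None -> (N, F, Ho, Wo).
    Implemented via an explicit im2col gather so the backward pass is a
    plain col2im scatter-add.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.shape
    f, c2, k, k2 = w.shape
    if c != c2 or k != k2:
        raise ValueError(f"conv2d shape mismatch: x channels {c}, w {w.shape}")
    ho = (h - k) // stride + 1
    wo = (wd - k) // stride + 1
    # index grids: (k*k, ho*wo)
    i0 = np.repeat(np.arange(k), k)[:, None] + stride * np.repeat(
        np.arange(ho), wo)[None, :]
    j0 = np.tile(np.arange(k), k)[:, None] + stride * np.tile(
        np.arange(wo), ho)[None, :]
    cols = x.data[:, :, i0, j0]                      # (n, c, k*k, ho*wo)
    cols2 = cols.reshape(n, c * k * k, ho * wo)
    wmat = w.data.reshape(f, c * k * k)
    out = np.einsum("fp,npl->nfl", wmat, cols2).reshape(n, f, ho, wo)

    parents: list[Tensor] = [x, w]
    if b is not None:
        b = as_tensor(b)
        out = out + b.data[None, :, None, None]
        parents.append(b)

    def backward(g):
        gl = g.reshape(n, f, ho * wo)
        if w.requires_grad:
            gw = np.einsum("nfl,npl->fp", gl, cols2).reshape(w.shape)
            w._accumulate(gw)
        if x.requires_grad:
            gcols = np.einsum("fp,nfl->npl", wmat, gl).reshape(n, c, k * k,
                                                               ho * wo)
            gx = np.zeros_like(x.data)
            np.add.at(gx, (slice(None), slice(None), i0, j0), gcols)
            x._accumulate(gx)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, tuple(parents), backward)


# ---------------------------------------------------------------------------
# parameter containers


def init_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                 fan_in: int) -> Tensor:
    """Seeded uniform fan-in initialisation, U(-1/sqrt(fan_in), +1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear:
    """Affine map y = x W + b with seeded initialisation."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = init_uniform(rng, (in_dim, out_dim), in_dim)
        self.bias = init_uniform(rng, (out_dim,), in_dim) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = as_tensor(x) @ self.weight
        return y + self.bias if self.bias is not None else y

    def params(self, prefix: str = "") -> dict[str, Tensor]:
        out = {f"{prefix}weight": self.weight}
        if self.bias is not None:
            out[f"{prefix}bias"] = self.bias
        return out


class MLP:
    """Stack of Linear layers with ReLU between them (none after the last)."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output dims")
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x

    def params(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for i, layer in enumerate(self.layers):
            out.update(layer.params(f"{prefix}l{i}."))
        return out


class Adam:
    """Adam with decoupled weight decay (AdamW-style), float64 state."""

    def __init__(self, params: dict[str, Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def flatten_params(params: dict[str, Tensor]) -> np.ndarray:
    return np.concatenate([params[k].data.ravel() for k in sorted(params)])


def set_flat_params(params: dict[str, Tensor], flat: np.ndarray) -> None:
    i = 0
    for k in sorted(params):
        p = params[k]
        p.data = flat[i:i + p.data.size].reshape(p.data.shape).copy()
        i += p.data.size


def numeric_gradient(fn: Callable[[], float], params: dict[str, Tensor],
                     h: float = 1e-5,
                     coords: Iterable[tuple[str, int]] | None = None
                     ) -> dict[tuple[str, int], float]:
    """Central finite differences of ``fn`` w.r.t. selected flat coordinates.

    Used by tests as the independent oracle for analytic gradients.
    """
    out: dict[tuple[str, int], float] = {}
    if coords is None:
        coords = [(k, i) for k, p in params.items() for i in range(p.data.size)]
    for k, i in coords:
        p = params[k]
        flat = p.data.ravel()
        orig = flat[i]
        flat[i] = orig + h
        fp = fn()
        flat[i] = orig - h
        fm = fn()
        flat[i] = orig
        out[(k, i)] = (fp - fm) / (2 * h)
    return out
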