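"""A minimal reverse-mode automatic differentiation core on numpy arrays.

Just enough machinery for the scoring network: dense algebra, the gather /
scatter / segment reductions that message passing needs, and the pointwise
nonlinearities.  Everything is float64 and eager; ``Tensor.backward()``
walks the recorded tape in reverse topological order.  Correctness is
pinned by a finite-difference gradient check in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` back to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, n in enumerate(shape):
        if n == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self) -> int:
        return self.data.size

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- autodiff ------------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep for long tapes
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ------------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        return Tensor._make(self.data + other.data, (self, other), bwd)

    def __sub__(self, other: "Tensor") -> "Tensor":
        return self + (other * -1.0)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)
        return Tensor._make(self.data @ other.data, (self, other), bwd)

    def reshape(self, *shape) -> "Tensor":
        old = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))
        return Tensor._make(self.data.reshape(*shape), (self,), bwd)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# --- pointwise ---------------------------------------------------------------

def relu(t: Tensor) -> Tensor:
    mask = t.data > 0

    def bwd(g):
        if t.requires_grad:
            t._accumulate(g * mask)
    return Tensor._make(t.data * mask, (t,), bwd)


def leaky_relu(t: Tensor, slope: float = 0.2) -> Tensor:
    factor = np.where(t.data > 0, 1.0, slope)

    def bwd(g):
        if t.requires_grad:
            t._accumulate(g * factor)
    return Tensor._make(t.data * factor, (t,), bwd)


def exp(t: Tensor) -> Tensor:
    out_data = np.exp(t.data)

    def bwd(g):
        if t.requires_grad:
            t._accumulate(g * out_data)
    return Tensor._make(out_data, (t,), bwd)


def sigmoid(t: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-t.data))

    def bwd(g):
        if t.requires_grad:
            t._accumulate(g * s * (1.0 - s))
    return Tensor._make(s, (t,), bwd)


def softplus(t: Tensor) -> Tensor:
    """log(1 + e^x), computed stably; gradient is the logistic function."""
    out_data = np.logaddexp(0.0, t.data)
    s = 1.0 / (1.0 + np.exp(-t.data))

    def bwd(g):
        if t.requires_grad:
            t._accumulate(g * s)
    return Tensor._make(out_data, (t,), bwd)


# --- shape & indexing --------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])
    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), bwd)


def take(t: Tensor, index: np.ndarray) -> Tensor:
    """Row gather: ``out[k] = t[index[k]]``."""
    index = np.asarray(index, dtype=np.int64)

    def bwd(g):
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            np.add.at(acc, index, g)
            t._accumulate(acc)
    return Tensor._make(t.data[index], (t,), bwd)


# --- segment reductions ------------------------------------------------------

def segment_sum(t: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Row scatter-add: ``out[s] = sum of rows with segments == s``."""
    segments = np.asarray(segments, dtype=np.int64)
    out_data = np.zeros((num_segments,) + t.data.shape[1:])
    np.add.at(out_data, segments, t.data)

    def bwd(g):
        if t.requires_grad:
            t._accumulate(g[segments])
    return Tensor._make(out_data, (t,), bwd)


def segment_max(t: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Element-wise max over rows of each segment; empty segments give 0.

    The gradient routes to the first row attaining the max in each
    (segment, column) slot — the usual max-pool subgradient.
    """
    segments = np.asarray(segments, dtype=np.int64)
    x = t.data if t.data.ndim == 2 else t.data.reshape(len(t.data), 1)
    squeeze = t.data.ndim == 1
    n, c = x.shape
    out_data = np.full((num_segments, c), -np.inf)
    np.maximum.at(out_data, segments, x)
    empty = ~np.isfinite(out_data)
    out_data[empty] = 0.0

    # first row index achieving the max, per (segment, column)
    winner = np.full((num_segments, c), n, dtype=np.int64)
    rows = np.arange(n)[:, None]
    is_max = x == out_data[segments]
    candidate = np.where(is_max, rows, n)
    np.minimum.at(winner, segments, candidate)

    def bwd(g):
        if t.requires_grad:
            g2 = g if g.ndim == 2 else g.reshape(num_segments, 1)
            acc = np.zeros((n + 1, c))
            np.add.at(acc, (winner.ravel(), np.tile(np.arange(c), num_segments)),
                      np.where(empty, 0.0, g2).ravel())
            grad = acc[:n]
            t._accumulate(grad.reshape(t.data.shape))
    out = out_data[:, 0] if squeeze else out_data
    return Tensor._make(out, (t,), bwd)


def segment_mean(t: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Row-wise mean over each segment; empty segments give 0."""
    segments = np.asarray(segments, dtype=np.int64)
    counts = np.bincount(segments, minlength=num_segments).astype(float)
    counts[counts == 0] = 1.0
    s = segment_sum(t, segments, num_segments)
    shape = (num_segments,) + (1,) * (t.data.ndim - 1)
    return s * Tensor(1.0 / counts.reshape(shape))


def segment_softmax(t: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a 1-D tensor within each segment (numerically shifted)."""
    segments = np.asarray(segments, dtype=np.int64)
    if t.data.ndim != 1:
        raise ValueError("segment_softmax expects a 1-D tensor")
    shift = np.full(num_segments, -np.inf)
    np.maximum.at(shift, segments, t.data)
    shift[~np.isfinite(shift)] = 0.0  # empty segments never indexed below

    e = exp(t + Tensor(-shift[segments]))
    denom = segment_sum(e, segments, num_segments)
    return e * gather_reciprocal(denom, segments)


def gather_reciprocal(t: Tensor, index: np.ndarray) -> Tensor:
    """``1 / t[index]`` for a 1-D positive tensor (softmax denominators)."""
    index = np.asarray(index, dtype=np.int64)
    vals = t.data[index]
    out_data = 1.0 / vals

    def bwd(g):
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            np.add.at(acc, index, -g / (vals * vals))
            t._accumulate(acc)
    return Tensor._make(out_data, (t,), bwd)


# --- reductions / losses -----------------------------------------------------

def mean(t: Tensor) -> Tensor:
    n = t.data.size

    def bwd(g):
        if t.requires_grad:
            t._accumulate(np.full_like(t.data, float(g) / n))
    return Tensor._make(t.data.mean(), (t,), bwd)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred + Tensor(-np.asarray(target, float))
    return mean(diff * diff)


def bce_with_logits_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """Binary cross-entropy on raw scores: mean(softplus(x) - x*y)."""
    y = np.asarray(target, float)
    return mean(softplus(logits) + logits * Tensor(-y))
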