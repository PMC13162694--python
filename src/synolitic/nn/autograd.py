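"""Minimal vectorized reverse-mode autodiff on numpy arrays.

Supports exactly the operations the graph networks need: broadcast
arithmetic, matmul, pointwise nonlinearities, reductions, gather /
segment-scatter (the message-passing primitives), concatenation, and a
fused weighted softmax cross-entropy.  Gradients are checked against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "gather",
    "segment_sum",
    "segment_max",
    "segment_softmax",
    "spmm",
    "repeat_cols",
    "block_mean_cols",
    "concat",
    "relu",
    "leaky_relu",
    "sigmoid",
    "softplus",
    "exp",
    "log",
    "sqrt",
    "mean",
    "total_sum",
    "softmax_cross_entropy",
]


_DEFAULT_DTYPE = np.float32
_GRAD_ENABLED = True


def set_default_dtype(dtype) -> None:
    """Set the engine's array dtype (float32 default; float64 for checks)."""
    global _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type


def default_dtype():
    return _DEFAULT_DTYPE


class no_grad:
    """Context manager disabling graph construction (for prediction)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _wrap(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, _wrap(-1.0)))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __neg__(self):
        return mul(self, _wrap(-1.0))


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else constant(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(
        data,
        requires_grad=_GRAD_ENABLED and any(p.requires_grad for p in parents),
    )
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = _unbroadcast(g, t.data.shape).astype(t.data.dtype, copy=False)
    t.grad = g if t.grad is None else t.grad + g


# -- arithmetic -----------------------------------------------------------
def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, g)
        _accum(b, g)

    return _make(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    return _make(a.data * b.data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, g / b.data)
        _accum(b, -g * a.data / (b.data**2))

    return _make(a.data / b.data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _make(a.data @ b.data, (a, b), backward)


# -- nonlinearities -------------------------------------------------------
def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        _accum(x, g * mask)

    return _make(x.data * mask, (x,), backward)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    one = x.data.dtype.type(1.0)
    mask = np.where(x.data > 0, one, x.data.dtype.type(slope))

    def backward(g):
        _accum(x, g * mask)

    return _make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def backward(g):
        _accum(x, g * s * (1.0 - s))

    return _make(s, (x,), backward)


def softplus(x: Tensor) -> Tensor:
    out = np.logaddexp(0.0, x.data)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def backward(g):
        _accum(x, g * s)

    return _make(out, (x,), backward)


def exp(x: Tensor) -> Tensor:
    e = np.exp(np.clip(x.data, -700, 700))

    def backward(g):
        _accum(x, g * e)

    return _make(e, (x,), backward)


def log(x: Tensor) -> Tensor:
    def backward(g):
        _accum(x, g / x.data)

    return _make(np.log(x.data), (x,), backward)


def sqrt(x: Tensor) -> Tensor:
    r = np.sqrt(x.data)

    def backward(g):
        _accum(x, g * 0.5 / r)

    return _make(r, (x,), backward)


# -- reductions -----------------------------------------------------------
def mean(x: Tensor, axis: int = 0, keepdims: bool = True) -> Tensor:
    n = x.data.shape[axis]

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(x, np.broadcast_to(g / n, x.data.shape))

    return _make(x.data.mean(axis=axis, keepdims=keepdims), (x,), backward)


def total_sum(x: Tensor) -> Tensor:
    def backward(g):
        _accum(x, np.broadcast_to(g, x.data.shape))

    return _make(np.array(x.data.sum()), (x,), backward)


# -- structure ops --------------------------------------------------------
def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather ``x[idx]`` with scatter-add backward."""
    idx = np.asarray(idx, dtype=int)

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, idx, g)
            _accum(x, gx)

    return _make(x.data[idx], (x,), backward)


def segment_sum(x: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given by ``segments``."""
    segments = np.asarray(segments, dtype=int)
    out = np.zeros((n_segments,) + x.data.shape[1:], dtype=x.data.dtype)
    np.add.at(out, segments, x.data)

    def backward(g):
        _accum(x, g[segments])

    return _make(out, (x,), backward)


def segment_max(x: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Per-segment max; gradient routes to the first attaining row."""
    segments = np.asarray(segments, dtype=int)
    out = np.full((n_segments,) + x.data.shape[1:], -np.inf, dtype=x.data.dtype)
    np.maximum.at(out, segments, x.data)

    def backward(g):
        if not x.requires_grad:
            return
        n_rows = x.data.shape[0]
        hit = x.data == out[segments]
        order = np.arange(n_rows).reshape((n_rows,) + (1,) * (x.data.ndim - 1))
        candidate = np.where(hit, np.broadcast_to(order, x.data.shape), n_rows)
        first = np.full(out.shape, n_rows, dtype=int)
        np.minimum.at(first, segments, candidate)
        gx = np.zeros_like(x.data)
        pos = np.nonzero(first < n_rows)
        gx[(first[pos],) + pos[1:]] += g[pos]
        _accum(x, gx)

    return _make(out, (x,), backward)


def spmm(s, x: Tensor, s_t) -> Tensor:
    """Sparse @ dense with a constant sparse matrix ``s`` (``s_t`` = s.T).

    Covers row gather (selection matrix) and segment scatter-sum
    (transposed selection matrix) far faster than fancy-indexing with
    ``np.add.at`` backward.
    """

    def backward(g):
        _accum(x, s_t @ g)

    return _make(s @ x.data, (x,), backward)


def segment_softmax(score: Tensor, segments: np.ndarray, n_segments: int,
                    scatter=None, gather_mat=None) -> Tensor:
    """Softmax of ``score`` within each segment (attention normalisation).

    ``scatter``/``gather_mat`` are optional precomputed (segments x rows)
    and (rows x segments) selection matrices used to speed up the
    normalisation; semantics are identical without them.
    """
    segments = np.asarray(segments, dtype=int)
    m = np.full((n_segments,) + score.data.shape[1:], -np.inf, dtype=score.data.dtype)
    np.maximum.at(m, segments, score.data)
    # shifting by the (detached) per-segment max is exact for softmax
    shifted = add(score, constant(-m[segments]))
    e = exp(shifted)
    if scatter is not None:
        denom = spmm(scatter, e, gather_mat)
        return div(e, spmm(gather_mat, denom, scatter))
    denom = segment_sum(e, segments, n_segments)
    return div(e, gather(denom, segments))



def repeat_cols(x: Tensor, k: int) -> Tensor:
    """Repeat each column ``k`` times (expand per-head scalars to blocks)."""

    def backward(g):
        _accum(x, g.reshape(g.shape[0], x.data.shape[1], k).sum(axis=2))

    return _make(np.repeat(x.data, k, axis=1), (x,), backward)


def block_mean_cols(x: Tensor, blocks: int) -> Tensor:
    """Mean over ``blocks`` equal column blocks (head averaging)."""
    n, d = x.data.shape
    w = d // blocks

    def backward(g):
        _accum(x, np.tile(g, (1, blocks)) / blocks)

    out = x.data.reshape(n, blocks, w).mean(axis=1)
    return _make(out, (x,), backward)


def softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, class_weights: np.ndarray
) -> Tensor:
    """Weighted mean cross-entropy over rows of 2-class ``logits``."""
    labels = np.asarray(labels, dtype=int)
    w = np.asarray(class_weights, dtype=np.float64)[labels]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    logp = z - np.log(ez.sum(axis=1, keepdims=True))
    loss = -(w * logp[np.arange(n), labels]).sum() / w.sum()

    def backward(g):
        onehot = np.zeros_like(p)
        onehot[np.arange(n), labels] = 1.0
        _accum(logits, g * (w[:, None] * (p - onehot)) / w.sum())

    return _make(np.array(loss), (logits,), backward)


def softmax_rows(logits: np.ndarray) -> np.ndarray:
    """Plain (non-differentiated) row softmax for prediction."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)
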