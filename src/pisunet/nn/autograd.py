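"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
``Tensor.backward()`` walks the recorded graph in reverse topological order
and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the operations the segmentation networks need
are provided (elementwise arithmetic, activations, reductions, reshaping,
concatenation, dense matmul); convolution, pooling and resampling live in
:mod:`pisunet.nn.functional`.

Float32 is the working precision; gradient-check tests build float64 tensors
and every op preserves the input dtype.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "make_node", "accumulate", "unbroadcast", "concat"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ info
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        accumulate(self, np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------ operators
    def __add__(self, other):
        return add(self, _as_tensor(other, self.dtype))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other, self.dtype))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, _as_tensor(-1.0, self.dtype))

    def __sub__(self, other):
        return add(self, -_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return add(_as_tensor(other, self.dtype), -self)

    def __truediv__(self, other):
        other = _as_tensor(other, self.dtype)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other, self.dtype), power(self, -1.0))

    def __pow__(self, exponent: float):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other, self.dtype))

    # --------------------------------------------------------------- methods
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def transpose2d(self):
        return transpose2d(self)


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def make_node(data: np.ndarray, parents: tuple, backward) -> Tensor:
    """Create a graph node; drops the tape when no parent needs gradients."""
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def accumulate(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ------------------------------------------------------------------ primitives

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        accumulate(a, unbroadcast(g, a.shape))
        accumulate(b, unbroadcast(g, b.shape))

    return make_node(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        accumulate(a, unbroadcast(g * b.data, a.shape))
        accumulate(b, unbroadcast(g * a.data, b.shape))

    return make_node(a.data * b.data, (a, b), backward)


def power(a: Tensor, exponent: float) -> Tensor:
    out_data = a.data ** exponent

    def backward(g):
        accumulate(a, g * exponent * a.data ** (exponent - 1.0))

    return make_node(out_data, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        accumulate(a, g / a.data)

    return make_node(np.log(a.data), (a,), backward)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        accumulate(a, g * out_data)

    return make_node(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        accumulate(a, g * mask)

    return make_node(np.where(mask, a.data, 0), (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable two-sided form
    x = a.data
    out_data = np.empty_like(x)
    pos = x >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out_data[~pos] = ex / (1.0 + ex)

    def backward(g):
        accumulate(a, g * out_data * (1.0 - out_data))

    return make_node(out_data, (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        accumulate(a, g * mask)

    return make_node(np.clip(a.data, lo, hi), (a,), backward)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            accumulate(a, np.broadcast_to(g, a.shape).astype(a.dtype, copy=True))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        accumulate(a, np.broadcast_to(g, a.shape).astype(a.dtype, copy=True))

    return make_node(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), _as_tensor(1.0 / n, a.dtype))


def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape

    def backward(g):
        accumulate(a, g.reshape(old))

    return make_node(a.data.reshape(shape), (a,), backward)


def transpose2d(a: Tensor) -> Tensor:
    def backward(g):
        accumulate(a, g.T)

    return make_node(a.data.T, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product."""
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")

    def backward(g):
        accumulate(a, g @ b.data.T)
        accumulate(b, a.data.T @ g)

    return make_node(a.data @ b.data, (a, b), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map ``x @ w.T + b`` for ``x`` of shape (N, in), ``w`` (out, in)."""
    out_data = x.data @ w.data.T
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        accumulate(x, g @ w.data)
        accumulate(w, g.T @ x.data)
        if b is not None:
            accumulate(b, g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return make_node(out_data, parents, backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            accumulate(t, g[tuple(idx)])

    return make_node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)
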