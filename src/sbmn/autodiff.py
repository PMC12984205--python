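"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network in this package is small (linear layers, patch convolutions,
softmax gating, sigmoids) and runs on one CPU, so a compact tape-based
engine is sufficient: every op records its parents and a closure that
pushes the upstream gradient back to them.  All arithmetic is float64.

Only the ops the model needs are provided; gradients are verified against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "matmul",
    "transpose",
    "permute",
    "reshape",
    "concat",
    "relu",
    "sigmoid",
    "log",
    "exp",
    "neg",
    "div",
    "square",
    "sqrt",
    "clip_min",
    "tsum",
    "tmean",
    "softmax",
    "scale",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad", "name")

    def __init__(self, value, parents=(), backward=None, requires_grad=False, name=""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self.parents)
        self.name = name

    @property
    def shape(self):
        return self.value.shape

    def detach(self) -> np.ndarray:
        return self.value.copy()

    # -- graph traversal -------------------------------------------------

    def backward(self, grad=None):
        """Accumulate d(self)/d(leaf) into every reachable leaf's ``.grad``."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; recursion depth is unbounded in long graphs
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad = self.grad + grad

    # -- operator sugar --------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return neg(self)

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _binary(a, b, value, da, db):
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(da(g), a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(db(g), b.value.shape))

    return Tensor(value, (a, b), backward)


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.value + b.value, lambda g: g, lambda g: g)


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.value - b.value, lambda g: g, lambda g: -g)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.value * b.value,
                   lambda g: g * b.value, lambda g: g * a.value)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.value @ b.value,
                   lambda g: g @ b.value.T, lambda g: a.value.T @ g)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.value / b.value,
                   lambda g: g / b.value,
                   lambda g: -g * a.value / (b.value ** 2))


def scale(a, c: float):
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * c)

    return Tensor(a.value * c, (a,), backward)


def _unary(a, value, da):
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(da(g))

    return Tensor(value, (a,), backward)


def neg(a):
    return scale(a, -1.0)


def transpose(a):
    a = as_tensor(a)
    return _unary(a, a.value.T, lambda g: g.T)


def reshape(a, shape):
    a = as_tensor(a)
    old = a.value.shape
    return _unary(a, a.value.reshape(shape), lambda g: g.reshape(old))


def permute(a, axes):
    a = as_tensor(a)
    inv = np.argsort(axes)
    return _unary(a, np.transpose(a.value, axes),
                  lambda g: np.transpose(g, inv))


def relu(a):
    a = as_tensor(a)
    mask = a.value > 0
    return _unary(a, a.value * mask, lambda g: g * mask)


def sigmoid(a):
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.value))
    return _unary(a, out, lambda g: g * out * (1.0 - out))


def log(a):
    a = as_tensor(a)
    return _unary(a, np.log(a.value), lambda g: g / a.value)


def exp(a):
    a = as_tensor(a)
    out = np.exp(a.value)
    return _unary(a, out, lambda g: g * out)


def square(a):
    a = as_tensor(a)
    return _unary(a, a.value ** 2, lambda g: g * 2.0 * a.value)


def sqrt(a):
    a = as_tensor(a)
    out = np.sqrt(a.value)
    return _unary(a, out, lambda g: g * 0.5 / out)


def clip_min(a, low: float):
    """max(a, low) elementwise; gradient passes only where a > low, so a
    clamped probability contributes a finite, constant loss term."""
    a = as_tensor(a)
    mask = a.value > low
    return _unary(a, np.maximum(a.value, low), lambda g: g * mask)


def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = a.value.sum(axis=axis, keepdims=keepdims)

    def da(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, a.value.shape).copy()

    return _unary(a, out, da)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.value.size if axis is None else a.value.shape[axis]
    return scale(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def softmax(a, axis: int):
    """Numerically stable softmax along ``axis`` with an exact closed-form
    backward (avoids building the exp/sum subgraph)."""
    a = as_tensor(a)
    z = a.value - a.value.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def da(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return out * (g - dot)

    return _unary(a, out, da)


def concat(tensors, axis: int):
    tensors = [as_tensor(t) for t in tensors]
    value = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(value, tuple(tensors), backward)
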