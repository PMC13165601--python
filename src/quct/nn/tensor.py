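"""Reverse-mode automatic differentiation on numpy arrays.

A minimal define-by-run autograd engine: every operation builds a node
holding its inputs and a closure that accumulates gradients into them.
``Tensor.backward()`` runs a topological sort and applies the closures in
reverse order.  All arithmetic is float32 end to end, matching the
single-precision convention used for the measurement tensors.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float32)
        if data.dtype != np.float32:
            data = data.astype(np.float32)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and grad_enabled()
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None

    # -- convenience -------------------------------------------------------
    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # operators (thin wrappers over functional ops, defined below)
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        if isinstance(other, Tensor):
            return multiply(self, other)
        return mul(self, other)

    def __rmul__(self, other):
        return self.__mul__(other)

    def __neg__(self):
        return mul(self, -1.0)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if grad_enabled() and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient g down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise -----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward():
        if a.requires_grad:
            a.accumulate(_unbroadcast(out.grad, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(out.grad, b.shape))

    out = _make(out_data, (a, b), backward)
    return out


def mul(a: Tensor, scalar: float) -> Tensor:
    s = np.float32(scalar)
    out_data = a.data * s

    def backward():
        if a.requires_grad:
            a.accumulate(out.grad * s)

    out = _make(out_data, (a,), backward)
    return out


def multiply(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward():
        if a.requires_grad:
            a.accumulate(_unbroadcast(out.grad * b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(out.grad * a.data, b.shape))

    out = _make(out_data, (a, b), backward)
    return out


def power(a: Tensor, exponent: float) -> Tensor:
    out_data = a.data ** np.float32(exponent)

    def backward():
        if a.requires_grad:
            a.accumulate(out.grad * exponent * a.data ** np.float32(exponent - 1))

    out = _make(out_data, (a,), backward)
    return out


def log(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def backward():
        if a.requires_grad:
            a.accumulate(out.grad / a.data)

    out = _make(out_data, (a,), backward)
    return out


def selu(a: Tensor) -> Tensor:
    """Scaled exponential linear unit (self-normalizing activation)."""
    alpha = np.float32(1.6732632423543772)
    scale = np.float32(1.0507009873554805)
    sa = np.float32(scale * alpha)
    xd = a.data
    pos = xd > 0
    expm = np.exp(np.minimum(xd, np.float32(0.0)))
    out_data = np.where(pos, scale * xd, sa * (expm - np.float32(1.0)))

    def backward():
        if a.requires_grad:
            a.accumulate(out.grad * np.where(pos, scale, sa * expm))

    out = _make(out_data, (a,), backward)
    return out


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward():
        if a.requires_grad:
            a.accumulate(out.grad * out_data * (1 - out_data))

    out = _make(out_data, (a,), backward)
    return out


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only where unclipped."""
    out_data = np.clip(a.data, lo, hi)
    mask = ((a.data > lo) & (a.data < hi)).astype(np.float32)

    def backward():
        if a.requires_grad:
            a.accumulate(out.grad * mask)

    out = _make(out_data, (a,), backward)
    return out


# -- shape ops -------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def backward():
        if a.requires_grad:
            a.accumulate(out.grad.reshape(a.shape))

    out = _make(out_data, (a,), backward)
    return out


def transpose(a: Tensor, axes) -> Tensor:
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward():
        if a.requires_grad:
            a.accumulate(np.transpose(out.grad, inv))

    out = _make(out_data, (a,), backward)
    return out


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out_data.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate(out.grad[tuple(sl)])

    out = _make(out_data, tuple(tensors), backward)
    return out


def pad2d(a: Tensor, pads) -> Tensor:
    """Zero-pad the last two axes; pads = (top, bottom, left, right)."""
    t, b, l, r = pads
    width = [(0, 0)] * (a.ndim - 2) + [(t, b), (l, r)]
    out_data = np.pad(a.data, width)
    H, W = a.shape[-2], a.shape[-1]

    def backward():
        if a.requires_grad:
            sl = (Ellipsis, slice(t, t + H), slice(l, l + W))
            a.accumulate(out.grad[sl])

    out = _make(out_data, (a,), backward)
    return out


def reduce_sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward():
        if a.requires_grad:
            g = out.grad
            if not keepdims and axis is not None:
                axes = (axis,) if isinstance(axis, int) else axis
                for ax in sorted(axes):
                    g = np.expand_dims(g, ax)
            a.accumulate(np.broadcast_to(g, a.shape))

    out = _make(np.asarray(out_data, dtype=np.float32), (a,), backward)
    return out


def reduce_mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else axis
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(reduce_sum(a, axis, keepdims), 1.0 / n)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward():
        if a.requires_grad:
            a.accumulate(out.grad @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ out.grad)

    out = _make(out_data, (a, b), backward)
    return out


def softmax(a: Tensor, axis: int = 1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward():
        if a.requires_grad:
            g = out.grad
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a.accumulate(out_data * (g - dot))

    out = _make(out_data.astype(np.float32), (a,), backward)
    return out
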