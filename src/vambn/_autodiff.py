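"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the heterogeneous-data VAE needs: affine
maps, pointwise nonlinearities, reductions and log-sum-exp, all with numpy
broadcasting. Gradients accumulate into ``Var.grad`` after ``backward()``.

This is intentionally a micro-engine: no graphs survive across calls, no
in-place ops, float64 throughout (the models here are tiny and benefit more
from numerical robustness than from speed).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Var", "concat", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Var:
    """A node in the computation tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward")
    __array_priority__ = 100  # make ndarray.__mul__ defer to Var.__rmul__

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph mechanics ---------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Var] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topo sort (graphs can be deepish)
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in order:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Var) else Var(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Var._lift(other)
        out = Var(self.data + other.data, (self, other))

        def bwd(g):
            self.grad += _unbroadcast(g, self.data.shape)
            other.grad += _unbroadcast(g, other.data.shape)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Var(-self.data, (self,))
        out._backward = lambda g: self.grad.__iadd__(-g)
        return out

    def __sub__(self, other):
        return self + (-Var._lift(other))

    def __rsub__(self, other):
        return Var._lift(other) + (-self)

    def __mul__(self, other):
        other = Var._lift(other)
        out = Var(self.data * other.data, (self, other))

        def bwd(g):
            self.grad += _unbroadcast(g * other.data, self.data.shape)
            other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Var._lift(other)
        out = Var(self.data / other.data, (self, other))

        def bwd(g):
            self.grad += _unbroadcast(g / other.data, self.data.shape)
            other.grad += _unbroadcast(
                -g * self.data / other.data**2, other.data.shape
            )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return Var._lift(other) / self

    def __matmul__(self, other):
        other = Var._lift(other)
        out = Var(self.data @ other.data, (self, other))

        def bwd(g):
            self.grad += _unbroadcast(
                g @ np.swapaxes(other.data, -1, -2), self.data.shape
            )
            other.grad += _unbroadcast(
                np.swapaxes(self.data, -1, -2) @ g, other.data.shape
            )

        out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = Var(self.data**p, (self,))
        out._backward = lambda g: self.grad.__iadd__(g * p * self.data ** (p - 1))
        return out

    # -- pointwise nonlinearities -----------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = Var(e, (self,))
        out._backward = lambda g: self.grad.__iadd__(g * e)
        return out

    def log(self):
        out = Var(np.log(self.data), (self,))
        out._backward = lambda g: self.grad.__iadd__(g / self.data)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Var(t, (self,))
        out._backward = lambda g: self.grad.__iadd__(g * (1.0 - t * t))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Var(s, (self,))
        out._backward = lambda g: self.grad.__iadd__(g * s * (1.0 - s))
        return out

    def softplus(self):
        # stable: log(1 + e^x) = max(x,0) + log1p(e^{-|x|})
        d = self.data
        val = np.maximum(d, 0.0) + np.log1p(np.exp(-np.abs(d)))
        out = Var(val, (self,))
        sig = 1.0 / (1.0 + np.exp(-np.clip(d, -60, 60)))
        out._backward = lambda g: self.grad.__iadd__(g * sig)
        return out

    def clip(self, lo: float, hi: float):
        """Value clipping with straight-through zero gradient outside range."""
        inside = (self.data >= lo) & (self.data <= hi)
        out = Var(np.clip(self.data, lo, hi), (self,))
        out._backward = lambda g: self.grad.__iadd__(g * inside)
        return out

    # -- reductions & reshaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Var(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Var(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self.grad.__iadd__(g.reshape(self.data.shape))
        return out

    def __getitem__(self, idx):
        out = Var(self.data[idx], (self,))

        def bwd(g):
            np.add.at(self.grad, idx, g)

        out._backward = bwd
        return out


def concat(vars_: list[Var], axis: int = 1) -> Var:
    vars_ = [Var._lift(v) for v in vars_]
    out = Var(np.concatenate([v.data for v in vars_], axis=axis), tuple(vars_))
    sizes = [v.data.shape[axis] for v in vars_]
    offs = np.cumsum([0] + sizes)

    def bwd(g):
        for v, a, b in zip(vars_, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            v.grad += g[tuple(sl)]

    out._backward = bwd
    return out


def logsumexp(v: Var, axis: int = 1, keepdims: bool = False) -> Var:
    m = v.data.max(axis=axis, keepdims=True)
    e = np.exp(v.data - m)
    s = e.sum(axis=axis, keepdims=True)
    val = m + np.log(s)
    if not keepdims:
        val = np.squeeze(val, axis=axis)
    out = Var(val, (v,))
    soft = e / s

    def bwd(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        v.grad += gg * soft

    out._backward = bwd
    return out
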