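"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports the operations the sequence-regression architectures need:
broadcasting arithmetic, (batched) matmul, element-wise nonlinearities,
reductions, reshape/transpose/concat, embedding lookup, softmax and layer
normalization. Gradients are accumulated in float64; correctness is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # --- graph bookkeeping ------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _child(self, data, prev) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        out._prev = tuple(p for p in prev if p.requires_grad)
        return out

    def _acc(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # --- arithmetic -------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = self._child(self.data + other.data, (self, other))

        def backward():
            if self.requires_grad:
                self._acc(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(out.grad, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = self._child(self.data * other.data, (self, other))

        def backward():
            if self.requires_grad:
                self._acc(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out = self._child(self.data**exponent, (self,))

        def backward():
            self._acc(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        out = self._child(a @ b, (self, other))

        def backward():
            g = out.grad
            if a.ndim == 1 and b.ndim == 1:  # inner product
                ga, gb = g * b, g * a
            elif a.ndim == 1:  # (k,) @ (..., k, m) -> (..., m)
                ga = (g[..., None, :] * b).sum(axis=-1)
                gb = np.multiply.outer(a, g) if b.ndim == 2 else a[:, None] * g[..., None, :]
            elif b.ndim == 1:  # (..., n, k) @ (k,) -> (..., n)
                ga = np.multiply.outer(g, b) if a.ndim == 2 else g[..., None] * b
                gb = np.tensordot(g, a, axes=(range(g.ndim), range(g.ndim)))
            else:  # (..., n, k) @ (..., k, m)
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            if self.requires_grad:
                self._acc(_unbroadcast(np.asarray(ga), self.shape))
            if other.requires_grad:
                other._acc(_unbroadcast(np.asarray(gb), other.shape))

        out._backward = backward
        return out

    # --- nonlinearities ---------------------------------------------------

    def tanh(self) -> "Tensor":
        out = self._child(np.tanh(self.data), (self,))

        def backward():
            self._acc(out.grad * (1.0 - out.data**2))

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = self._child(s, (self,))

        def backward():
            self._acc(out.grad * out.data * (1.0 - out.data))

        out._backward = backward
        return out

    def relu(self) -> "Tensor":
        out = self._child(np.maximum(self.data, 0.0), (self,))

        def backward():
            self._acc(out.grad * (self.data > 0))

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        out = self._child(np.exp(self.data), (self,))

        def backward():
            self._acc(out.grad * out.data)

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = self._child(np.log(self.data), (self,))

        def backward():
            self._acc(out.grad / self.data)

        out._backward = backward
        return out

    # --- reductions and shaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._child(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        out = self._child(self.data.reshape(*shape), (self,))

        def backward():
            self._acc(out.grad.reshape(self.shape))

        out._backward = backward
        return out

    def transpose(self, axes) -> "Tensor":
        out = self._child(self.data.transpose(axes), (self,))
        inv = np.argsort(axes)

        def backward():
            self._acc(out.grad.transpose(inv))

        out._backward = backward
        return out

    def __getitem__(self, key) -> "Tensor":
        out = self._child(self.data[key], (self,))

        def backward():
            g = np.zeros_like(self.data)
            g[key] = out.grad
            self._acc(g)

        out._backward = backward
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = self._child(s, (self,))

        def backward():
            g = out.grad
            dot = (g * out.data).sum(axis=axis, keepdims=True)
            self._acc(out.data * (g - dot))

        out._backward = backward
        return out


def concat(tensors: list, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    out._prev = tuple(t for t in tensors if t.requires_grad)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._acc(out.grad[tuple(idx)])

    out._backward = backward
    return out


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Look up rows of `weight` (vocab, dim) by an integer index array."""
    indices = np.asarray(indices, dtype=np.int64)
    out = Tensor(weight.data[indices])
    out.requires_grad = weight.requires_grad
    out._prev = (weight,) if weight.requires_grad else ()

    def backward():
        g = np.zeros_like(weight.data)
        np.add.at(g, indices.reshape(-1), out.grad.reshape(-1, weight.data.shape[1]))
        weight._acc(g)

    out._backward = backward
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps).pow(-0.5) * gamma + beta


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(target, dtype=np.float64))
    return (diff * diff).mean()
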