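"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module provides just enough machinery to express and train the two
attention-based bag classifiers in this package: dense layers, the usual
activations, softmax attention, set-level reductions (mean / variance /
power mean / max) and a cross-entropy loss.  Tensors wrap float64 numpy
arrays; calling :meth:`Tensor.backward` on a scalar loss accumulates
gradients into every reachable tensor with ``requires_grad=True``.

Broadcasting in elementwise ops is supported; gradients are un-broadcast
(summed over expanded axes) on the way back.  Gradient correctness is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "Adam"]

_SQRT2 = float(np.sqrt(2.0))
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes where shape had size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @staticmethod
    def const(data) -> "Tensor":
        return Tensor(data, requires_grad=False)

    @property
    def shape(self):
        return self.data.shape

    # ---- graph traversal -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- elementwise arithmetic -----------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor.const(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += -g

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(-g * self.data / other.data ** 2,
                                           other.data.shape)

        out._backward = bwd
        return out

    def pow(self, exponent: float) -> "Tensor":
        """Elementwise power with a constant exponent."""
        out = Tensor(self.data ** exponent, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * exponent * self.data ** (exponent - 1.0)

        out._backward = bwd
        return out

    # ---- linear algebra --------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g

        out._backward = bwd
        return out

    __matmul__ = matmul

    def transpose(self) -> "Tensor":
        out = Tensor(self.data.T, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g.T

        out._backward = bwd
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g.reshape(orig)

        out._backward = bwd
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                np.add.at(self.grad, idx, g)

        out._backward = bwd
        return out

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max reduction; ties send their gradient to the first arg-max."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.max(self.data, axis=axis, keepdims=keepdims)
        out = Tensor(out_data, parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            gg = g if not keepdims else np.squeeze(g, axis=axis)
            grad = np.zeros_like(self.data)
            grid = np.indices(idx.shape)
            full = list(grid)
            full.insert(axis, idx)
            grad[tuple(full)] = gg
            self.grad += grad

        out._backward = bwd
        return out

    # ---- nonlinearities --------------------------------------------------
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * out.data

        out._backward = bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g / self.data

        out._backward = bwd
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * (1.0 - out.data ** 2)

        out._backward = bwd
        return out

    def sigmoid(self) -> "Tensor":
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * out.data * (1.0 - out.data)

        out._backward = bwd
        return out

    def gelu(self) -> "Tensor":
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / _SQRT2))
        out = Tensor(x * phi, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                pdf = _INV_SQRT_2PI * np.exp(-0.5 * x ** 2)
                self.grad += g * (phi + x * pdf)

        out._backward = bwd
        return out

    def softplus(self) -> "Tensor":
        # numerically stable log(1 + exp(x))
        out = Tensor(np.logaddexp(0.0, self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g / (1.0 + np.exp(-self.data))

        out._backward = bwd
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                # J^T g = s * (g - sum(g * s))
                dot = (g * s).sum(axis=axis, keepdims=True)
                self.grad += s * (g - dot)

        out._backward = bwd
        return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    out._backward = bwd
    return out


class Adam:
    """Adam optimiser over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g ** 2
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
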