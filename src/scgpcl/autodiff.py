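"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate for the graph encoder, the ZINB decoder and
the contrastive/clustering losses.  It implements exactly the primitives the
model needs — elementwise arithmetic with broadcasting, dense and sparse
matrix products, exp/log/sigmoid/ELU, log-gamma, log-add-exp, reductions,
row gathering and clipping — plus an Adam optimizer.  Gradients of every
primitive are checked against central finite differences in the test suite.

Conventions
-----------
* ``Tensor`` wraps a float64 or float32 ndarray (training runs in single
  precision; everything else defaults to double).  Only tensors created
  with ``requires_grad=True`` (or depending on one) accumulate gradients.
* ``backward()`` may only be called on a scalar tensor.
* Constants (plain ndarrays / floats) may appear on either side of the
  arithmetic operators and are treated as non-differentiable.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln as _gammaln
from scipy.special import psi as _digamma

__all__ = ["Tensor", "Adam"]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype == np.float32:  # training runs in single precision
        return a
    return a.astype(np.float64) if a.dtype != np.float64 else a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple = ()

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _lift(x, dtype=None) -> "Tensor":
        """Wrap a constant.  Scalar constants adopt ``dtype`` so that python
        floats never promote a single-precision graph to double."""
        if isinstance(x, Tensor):
            return x
        a = np.asarray(x)
        if dtype is not None and a.ndim == 0 and a.dtype != dtype:
            a = a.astype(dtype)
        return Tensor(a)

    @classmethod
    def _make(cls, data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = cls(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; recursion depth is unbounded otherwise
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        # break closure reference cycles so large intermediates free
        # promptly by refcount instead of waiting for the cyclic collector
        for node in topo:
            node._backward = None
            node._prev = ()

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        a, b = self, self._lift(other, self.data.dtype)
        out = Tensor._make(a.data + b.data, (a, b), None)

        def bwd():
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad, b.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)

        def bwd():
            self._accum(-out.grad)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._lift(other, self.data.dtype))

    def __rsub__(self, other):
        return self._lift(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        a, b = self, self._lift(other, self.data.dtype)
        out = Tensor._make(a.data * b.data, (a, b), None)

        def bwd():
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad * a.data, b.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, self._lift(other, self.data.dtype)
        out = Tensor._make(a.data / b.data, (a, b), None)

        def bwd():
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-out.grad * a.data / b.data**2, b.data.shape))

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other, self.data.dtype) / self

    def __pow__(self, p: float):
        out = Tensor._make(self.data**p, (self,), None)

        def bwd():
            self._accum(out.grad * p * self.data ** (p - 1))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        a, b = self, self._lift(other)
        out = Tensor._make(a.data @ b.data, (a, b), None)

        def bwd():
            if a.requires_grad:
                a._accum(out.grad @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ out.grad)

        out._backward = bwd
        return out

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        out = Tensor._make(np.exp(self.data), (self,), None)

        def bwd():
            self._accum(out.grad * out.data)

        out._backward = bwd
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)

        def bwd():
            self._accum(out.grad / self.data)

        out._backward = bwd
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(s, (self,), None)

        def bwd():
            self._accum(out.grad * s * (1.0 - s))

        out._backward = bwd
        return out

    def elu(self, alpha: float = 1.0):
        x = self.data
        neg = alpha * np.expm1(np.minimum(x, 0.0))
        out = Tensor._make(np.where(x > 0, x, neg), (self,), None)

        def bwd():
            self._accum(out.grad * np.where(x > 0, 1.0, neg + alpha))

        out._backward = bwd
        return out

    def sqrt(self):
        return self**0.5

    def gammaln(self):
        out = Tensor._make(_gammaln(self.data), (self,), None)

        def bwd():
            self._accum(out.grad * _digamma(self.data))

        out._backward = bwd
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through inside [lo, hi] only."""
        lo, hi = float(lo), float(hi)  # weak scalars: no dtype promotion
        inside = (self.data >= lo) & (self.data <= hi)
        out = Tensor._make(np.clip(self.data, lo, hi), (self,), None)

        def bwd():
            self._accum(out.grad * inside)

        out._backward = bwd
        return out

    # -- reductions & shaping --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bwd():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def take_rows(self, idx: np.ndarray):
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor._make(self.data[idx], (self,), None)

        def bwd():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)

        out._backward = bwd
        return out

    @property
    def T(self):
        out = Tensor._make(self.data.T, (self,), None)

        def bwd():
            self._accum(out.grad.T)

        out._backward = bwd
        return out


# -- free functions -------------------------------------------------------

def spmm(A: sp.spmatrix, X: Tensor) -> Tensor:
    """Product of a constant sparse matrix with a dense tensor."""
    A = sp.csr_matrix(A)
    if A.dtype != X.data.dtype:
        A = A.astype(X.data.dtype)
    out = Tensor._make(A @ X.data, (X,), None)

    def bwd():
        X._accum(A.T @ out.grad)

    out._backward = bwd
    return out


def logaddexp(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise log(e^a + e^b), numerically stable, with softmax gradient."""
    a = Tensor._lift(a)
    b = Tensor._lift(b)
    val = np.logaddexp(a.data, b.data)
    wa = np.exp(a.data - val)  # softmax weights sum to 1
    wb = np.exp(b.data - val)
    out = Tensor._make(val, (a, b), None)

    def bwd():
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad * wa, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(out.grad * wb, b.data.shape))

    out._backward = bwd
    return out


def logsumexp_rows(x: Tensor) -> Tensor:
    """Row-wise log-sum-exp of a 2-D tensor, returned as shape (n, 1)."""
    m = x.data.max(axis=1, keepdims=True)  # constant shift, grad cancels
    return (x - m).exp().sum(axis=1, keepdims=True).log() + m


def normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Scale each row to unit L2 norm (cosine-similarity preprocessing)."""
    sq = (x * x).sum(axis=1, keepdims=True)
    return x / ((sq + eps) ** 0.5)


class Adam:
    """Adam optimizer over a list of Tensors (diagonal second moments)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params]
        if not all(p.requires_grad for p in self.params):
            raise ValueError("all optimized tensors must require gradients")
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
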