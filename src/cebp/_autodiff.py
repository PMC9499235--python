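"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the variational model in :mod:`cebp.cevae`:
elementwise arithmetic with numpy broadcasting, matrix multiplication,
reductions, and the handful of nonlinearities the networks use (ELU,
sigmoid, softplus, exp, log).  Gradients are accumulated by topological
traversal of the operation graph; broadcasting is undone on the way back by
summing over broadcast axes.  Correctness is pinned down by central
finite-difference checks in the test suite.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Tuple

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # collapse axes that were size-1 in the original
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph: an ndarray plus its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Tuple["Tensor", ...] = ()

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph construction helpers ------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, float), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data / other.data, self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / other.data**2)

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = backward
        return out

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * p * self.data ** (p - 1)
        )
        return out

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        out._parents = (self,)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g, float)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ---------------------------------------------------

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: self.requires_grad and self._accumulate(g * val)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g / self.data
        )
        return out

    def sigmoid(self) -> "Tensor":
        val = _sigmoid(self.data)
        out = Tensor(val, self.requires_grad)
        out._parents = (self,)
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * val * (1.0 - val)
        )
        return out

    def softplus(self) -> "Tensor":
        # stable: log(1 + e^x) = max(x, 0) + log1p(e^{-|x|})
        val = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        out = Tensor(val, self.requires_grad)
        out._parents = (self,)
        sig = _sigmoid(self.data)
        out._backward = lambda g: self.requires_grad and self._accumulate(g * sig)
        return out

    def elu(self, alpha: float = 1.0) -> "Tensor":
        neg = alpha * np.expm1(np.minimum(self.data, 0.0))
        val = np.where(self.data > 0, self.data, neg)
        out = Tensor(val, self.requires_grad)
        out._parents = (self,)
        deriv = np.where(self.data > 0, 1.0, neg + alpha)
        out._backward = lambda g: self.requires_grad and self._accumulate(g * deriv)
        return out

    # -- backward --------------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph.

        Gradients accumulate into ``.grad`` of every node that requires
        them; callers zero leaf gradients between steps.
        """
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        # iterative topological sort (graphs can be deep: depth x layers)
        order: List[Tensor] = []
        seen = set()
        stack: List[Tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def parameter(data, rng: Optional[np.random.Generator] = None) -> Tensor:
    return Tensor(np.asarray(data, float), requires_grad=True)


def zero_grads(params) -> None:
    for p in params:
        p.grad = None
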