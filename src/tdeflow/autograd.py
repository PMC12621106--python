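"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training procedure unrolls the detector recurrence in discrete time and
backpropagates through it (BPTT).  The only non-differentiable operation in
the whole pipeline is the Heaviside spike threshold; its backward pass is
replaced by a smooth surrogate derivative (see :func:`heaviside`).  Everything
else is ordinary elementwise arithmetic and reductions, so a small tape-based
engine is sufficient: each :class:`Var` records its parents and a closure that
accumulates gradients into them, and :meth:`Var.backward` walks the tape in
reverse topological order.

Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand's shape by :func:`_unbroadcast`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Var", "as_var", "heaviside", "sigmoid", "SURROGATE_BETA"]

#: Steepness of the surrogate spike derivative 1/(1 + beta*|x|)^2.
SURROGATE_BETA = 10.0


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Var:
    """A node in the computation tape: a numpy array plus gradient plumbing."""

    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, prev=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._prev = prev
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in prev)

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self):
        """Reverse-accumulate d(self)/d(leaf) for every reachable leaf."""
        topo, seen, stack = [], set(), [(self, False)]
        while stack:  # iterative DFS; sequences unroll to thousands of nodes
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- operators
    def __add__(self, other):
        other = as_var(other)
        out = Var(self.data + other.data, (self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_var(other)
        out = Var(self.data * other.data, (self, other))
        out._backward = lambda g: (
            self._accum(g * other.data),
            other._accum(g * self.data),
        )
        return out

    __rmul__ = __mul__

    def __neg__(self):
        out = Var(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_var(other))

    def __rsub__(self, other):
        return as_var(other) + (-self)

    def __truediv__(self, other):
        other = as_var(other)
        out = Var(self.data / other.data, (self, other))
        out._backward = lambda g: (
            self._accum(g / other.data),
            other._accum(-g * self.data / other.data**2),
        )
        return out

    def __rtruediv__(self, other):
        return as_var(other) / self

    def __pow__(self, k):
        assert np.isscalar(k)
        out = Var(self.data**k, (self,))
        out._backward = lambda g: self._accum(g * k * self.data ** (k - 1))
        return out

    # ------------------------------------------------------------- functions
    def exp(self):
        out = Var(np.exp(self.data), (self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Var(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        out = Var(np.sqrt(self.data), (self,))
        out._backward = lambda g: self._accum(g * 0.5 / np.maximum(out.data, 1e-30))
        return out

    def abs(self):
        out = Var(np.abs(self.data), (self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Var(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def _bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self):
        """Maximum over all elements; gradient routed to the argmax entry."""
        if self.data.ndim == 0:
            return self
        idx = np.unravel_index(int(np.argmax(self.data)), self.data.shape)
        out = Var(self.data.max(), (self,))

        def _bw(g):
            gg = np.zeros_like(self.data)
            gg[idx] = g
            self._accum(gg)

        out._backward = _bw
        return out

    def maximum(self, other):
        """Elementwise max; gradient routed to the winning operand."""
        other = as_var(other)
        out = Var(np.maximum(self.data, other.data), (self, other))
        mask = self.data >= other.data
        out._backward = lambda g: (
            self._accum(g * mask),
            other._accum(g * (~mask)),
        )
        return out

    def detach(self):
        return Var(self.data, requires_grad=False)


def as_var(x) -> Var:
    if isinstance(x, Var):
        return x
    return Var(x, requires_grad=False)


def heaviside(x: Var, beta: float = SURROGATE_BETA) -> Var:
    """Spike function: forward H(x) = 1[x >= 0], backward 1/(1 + beta*|x|)^2.

    The surrogate derivative is strictly positive and peaked at the threshold,
    so gradient information crosses the spiking nonlinearity even when the
    membrane potential is far from threshold.
    """
    x = as_var(x)
    out = Var((x.data >= 0).astype(np.float64), (x,))
    out._backward = lambda g: x._accum(g / (1.0 + beta * np.abs(x.data)) ** 2)
    return out


def sigmoid(x: Var) -> Var:
    x = as_var(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Var(s, (x,))
    out._backward = lambda g: x._accum(g * s * (1.0 - s))
    return out
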