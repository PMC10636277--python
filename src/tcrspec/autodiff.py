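"""Minimal reverse-mode automatic differentiation on numpy arrays.

The classification models in this package are small (hidden sizes of a few
dozen, a couple of transformer layers), so a compact tape-based autodiff over
``numpy.ndarray`` is sufficient and keeps the package free of deep-learning
framework dependencies.  Only the operations the models need are provided:
broadcasting arithmetic, batched matmul, reshape/transpose, relu/gelu/tanh,
exp/log/pow, reductions, embedding lookup, layer normalization, log-softmax,
dropout and position selection.

Gradient correctness is established by central-finite-difference checks in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were 1
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_unbroadcast(grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, out):
            self._accum(-grad)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_unbroadcast(grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e

        def backward(grad, out):
            self._accum(grad * e * self.data ** (e - 1.0))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(grad, out):
            if self.requires_grad:
                g = grad @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ grad
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    # -- shape ----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def backward(grad, out):
            self._accum(grad.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(grad, out):
            self._accum(np.swapaxes(grad, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), backward)

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(grad, out):
            self._accum(grad * mask)

        return self._make(self.data * mask, (self,), backward)

    def gelu(self):
        # tanh approximation (as used by BERT-family models)
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(grad, out):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            dout = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
            self._accum(grad * dout)

        return self._make(out_data, (self,), backward)

    def tanh(self):
        t = np.tanh(self.data)

        def backward(grad, out):
            self._accum(grad * (1.0 - t ** 2))

        return self._make(t, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(grad, out):
            self._accum(grad * e)

        return self._make(e, (self,), backward)

    def log(self):
        def backward(grad, out):
            self._accum(grad / self.data)

        return self._make(np.log(self.data), (self,), backward)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(grad, out):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- composite ops with bespoke vjps --------------------------------
    def log_softmax(self, axis: int = -1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        s = x - m
        lse = np.log(np.exp(s).sum(axis=axis, keepdims=True))
        ls = s - lse
        p = np.exp(ls)

        def backward(grad, out):
            self._accum(grad - p * grad.sum(axis=axis, keepdims=True))

        return self._make(ls, (self,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis, then scale and shift."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc ** 2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out_data = xhat * gamma.data + beta.data
        d = x.shape[-1]

        def backward(grad, out):
            if gamma.requires_grad:
                gamma._accum(
                    _unbroadcast(grad * xhat, gamma.data.shape))
            if beta.requires_grad:
                beta._accum(_unbroadcast(grad, beta.data.shape))
            if self.requires_grad:
                gx = grad * gamma.data
                term = gx - gx.mean(axis=-1, keepdims=True) \
                    - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                self._accum(term * inv)

        return self._make(out_data, (self, gamma, beta), backward)

    def take_rows(self, ids: np.ndarray):
        """Embedding lookup: self is a (V, d) table, ids an integer array.

        Returns a tensor of shape ids.shape + (d,).
        """
        ids = np.asarray(ids)
        out_data = self.data[ids]
        vocab = self.data.shape[0]

        def backward(grad, out):
            g = np.zeros_like(self.data)
            np.add.at(g, ids.reshape(-1), grad.reshape(-1, grad.shape[-1]))
            self._accum(g)

        return self._make(out_data, (self,), backward)

    def select_position(self, idx: np.ndarray):
        """Pick one sequence position per batch row: (B, L, d) -> (B, d)."""
        idx = np.asarray(idx)
        B = self.data.shape[0]
        out_data = self.data[np.arange(B), idx]

        def backward(grad, out):
            g = np.zeros_like(self.data)
            g[np.arange(B), idx] = grad
            self._accum(g)

        return self._make(out_data, (self,), backward)

    def dropout(self, p: float, rng: np.random.Generator | None):
        """Inverted dropout; identity when rng is None (eval mode) or p == 0."""
        if rng is None or p <= 0.0:
            return self
        keep = (rng.random(self.data.shape) >= p) / (1.0 - p)

        def backward(grad, out):
            self._accum(grad * keep)

        return self._make(self.data * keep, (self,), backward)

    # ------------------------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad, t)

    def zero_graph(self):  # pragma: no cover - debugging helper
        self._parents = ()
        self._backward = None


class Parameter(Tensor):
    """A trainable tensor, optionally with a gradient mask.

    ``grad_mask`` multiplies the accumulated gradient before an optimizer
    step; it is how padding rows of embedding tables stay frozen at zero.
    """

    __slots__ = ("grad_mask", "name")

    def __init__(self, data, name: str = "", grad_mask: np.ndarray | None = None):
        super().__init__(data, requires_grad=True)
        self.name = name
        self.grad_mask = None if grad_mask is None else np.asarray(grad_mask, dtype=np.float64)

    def masked_grad(self) -> np.ndarray:
        g = self.grad if self.grad is not None else np.zeros_like(self.data)
        if self.grad_mask is not None:
            g = g * self.grad_mask
        return g
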