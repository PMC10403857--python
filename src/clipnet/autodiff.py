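"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The profile model is a small stack of dilated convolutions, batch
normalisation and softmax-normalised output heads; every operation it needs
is expressible with the handful of primitives below.  Each primitive builds a
node in a DAG of :class:`Tensor` objects; calling :meth:`Tensor.backward` on a
scalar loss topologically sorts the graph and accumulates gradients into
``tensor.grad`` for every node with ``requires_grad``.

All arithmetic is float32 unless the caller passes float64 data; gradients
inherit the data dtype.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 stretched by broadcasting
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph construction helpers -----------------------------------------

    @classmethod
    def _node(cls, data, parents, backward):
        out = cls(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        """A constant view of this tensor: same data, no gradient flow."""
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):
            # keep python scalars weak so float32 graphs stay float32
            c = other
            return Tensor._node(self.data + c, (self,), lambda g: (g,))
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            c = other
            return Tensor._node(self.data * c, (self,), lambda g: (g * c,))
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other).power(-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self.power(-1.0)

    def power(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1.0),)

        return Tensor._node(out_data, (self,), backward)

    def matmul(self, weight: "Tensor") -> "Tensor":
        """``x @ W`` where ``x`` is (..., k) and ``W`` is a 2-D (k, m) matrix."""
        out_data = self.data @ weight.data

        def backward(g):
            gx = g @ weight.data.T
            k, m = weight.data.shape
            gw = self.data.reshape(-1, k).T @ g.reshape(-1, m)
            return gx, gw

        return Tensor._node(out_data, (self, weight), backward)

    # -- elementwise nonlinearities ------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._node(
            np.where(mask, self.data, 0.0), (self,), lambda g: (g * mask,)
        )

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        return Tensor._node(out_data, (self,), lambda g: (g * out_data,))

    def log(self) -> "Tensor":
        return Tensor._node(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._node(
            out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),)
        )

    # -- reductions and shape ops --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        return Tensor._node(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(self.shape),)
        )

    def pad1d(self, left: int, right: int, axis: int = 1) -> "Tensor":
        """Zero-pad along ``axis`` (used for same-padding convolutions)."""
        widths = [(0, 0)] * self.ndim
        widths[axis] = (left, right)
        out_data = np.pad(self.data, widths)
        sl = [slice(None)] * self.ndim
        sl[axis] = slice(left, left + self.shape[axis])
        sl = tuple(sl)
        return Tensor._node(out_data, (self,), lambda g: (g[sl],))

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data)
            full[key] = g
            return (full,)

        return Tensor._node(out_data, (self,), backward)

    # -- numerically stable composites ---------------------------------------

    def log_softmax(self, axis: int = 1) -> "Tensor":
        """log softmax along ``axis`` with the usual max-shift stabilisation."""
        shift = self.data.max(axis=axis, keepdims=True)
        z = self - Tensor(shift)
        return z - z.exp().sum(axis=axis, keepdims=True).log()

    @staticmethod
    def logaddexp(a: "Tensor", b: "Tensor") -> "Tensor":
        """Elementwise log(exp(a) + exp(b)), stable for large-magnitude inputs."""
        shift = Tensor(np.maximum(a.data, b.data))
        return ((a - shift).exp() + (b - shift).exp()).log() + shift

    # -- backward pass -------------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for parent, pg in zip(node._parents, parent_grads):
                if not parent.requires_grad or pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)
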