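"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records, when gradients are
enabled, the operation that produced it.  ``Tensor.backward()`` runs a
topological sweep over that tape.  Only the operations the segmentation
networks need are implemented: broadcast arithmetic, reductions, elementwise
nonlinearities, reshape/slice/concatenate, and (in :mod:`dtseg.nn.conv`)
3D convolutions and upsampling.

Design notes: gradients are accumulated densely in ``.grad``; broadcasting
is undone with a sum-to-shape rule; a global ``no_grad`` switch turns tape
construction off for frozen-network inference.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable tape construction inside the context (frozen forward passes)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def grad_enabled() -> bool:
    return _grad_enabled


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reverse numpy broadcasting: reduce ``grad`` back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.name = name

    # -- construction of graph nodes ------------------------------------
    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        rg = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=rg)
        if rg:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- backward sweep --------------------------------------------------
    def backward(self, grad=None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order (children before parents)
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
        # flush gradients of leaves already handled above via _backward=None

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        return Tensor._node(
            self.data + other.data,
            (self, other),
            lambda g: (
                _sum_to_shape(g, self.shape),
                _sum_to_shape(g, other.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        return Tensor._node(
            self.data * other.data,
            (self, other),
            lambda g: (
                _sum_to_shape(g * other.data, self.shape),
                _sum_to_shape(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return Tensor._node(
            self.data / other.data,
            (self, other),
            lambda g: (
                _sum_to_shape(g / other.data, self.shape),
                _sum_to_shape(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = self.data**exponent
        return Tensor._node(
            out,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __abs__(self):
        return Tensor._node(
            np.abs(self.data), (self,), lambda g: (g * np.sign(self.data),)
        )

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g2, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return Tensor._node(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ----------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._node(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._node(s, (self,), lambda g: (g * s * (1.0 - s),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor._node(e, (self,), lambda g: (g * e,))

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._node(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def __getitem__(self, index):
        out = self.data[index]

        def backward(g):
            full = np.zeros_like(self.data)
            full[index] = g
            return (full,)

        return Tensor._node(out, (self,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(data, tuple(tensors), backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax; the max-shift is a constant w.r.t. grads."""
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)
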