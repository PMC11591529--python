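"""Tensor type with a dynamically built backward graph.

Every differentiable op returns a new :class:`Tensor` holding references to
its parents and a closure mapping the output gradient to parent gradients.
``Tensor.backward`` runs the closures in reverse topological order. Data is
kept in float32; gradients accumulate in float32 arrays of matching shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "matmul", "softmax", "narrow"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = parents if self.requires_grad else ()
        self._backward_fn = backward_fn if self.requires_grad else None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- autograd ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient only on scalars")
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
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy()
            else:
                node.grad += g
            if node._backward_fn is None:
                continue
            parent_grads = node._backward_fn(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] += pg
                else:
                    grads[id(p)] = pg

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad
        if not req:
            return Tensor(out_data)

        def bwd(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        if not self.requires_grad:
            return Tensor(-self.data)
        return Tensor(-self.data, True, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad
        if not req:
            return Tensor(out_data)

        def bwd(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return Tensor(out_data, True, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data
        req = self.requires_grad or other.requires_grad
        if not req:
            return Tensor(out_data)

        def bwd(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape),
            )

        return Tensor(out_data, True, (self, other), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data**exponent
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            return (g * exponent * self.data ** (exponent - 1.0),)

        return Tensor(out_data, True, (self,), bwd)

    __pow__ = pow

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)
        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), lambda g: (g.reshape(orig),))

    def transpose(self, axes) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)
        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), lambda g: (g.transpose(inv),))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not self.requires_grad:
            return Tensor(out_data)
        shape = self.data.shape

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, shape).astype(np.float32),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, shape).astype(np.float32),)

        return Tensor(out_data, True, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)
        if not self.requires_grad:
            return Tensor(out_data)
        mask = (self.data > 0).astype(np.float32)
        return Tensor(out_data, True, (self,), lambda g: (g * mask,))

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), lambda g: (g * out_data,))

    def log(self) -> "Tensor":
        out_data = np.log(self.data)
        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), lambda g: (g / self.data,))

    def clip(self, lo: float, hi: float) -> "Tensor":
        out_data = np.clip(self.data, lo, hi)
        if not self.requires_grad:
            return Tensor(out_data)
        mask = ((self.data >= lo) & (self.data <= hi)).astype(np.float32)
        return Tensor(out_data, True, (self,), lambda g: (g * mask,))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not any(t.requires_grad for t in tensors):
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out_data, True, tuple(tensors), bwd)


def narrow(t: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice ``[start:start+length]`` along ``axis``."""
    idx = [slice(None)] * t.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out_data = t.data[idx]
    if not t.requires_grad:
        return Tensor(out_data)
    shape = t.data.shape

    def bwd(g):
        full = np.zeros(shape, dtype=np.float32)
        full[idx] = g
        return (full,)

    return Tensor(out_data, True, (t,), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product; batch dimensions must match exactly."""
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.matmul(a.data, b.data)
    if not (a.requires_grad or b.requires_grad):
        return Tensor(out_data)

    def bwd(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

    return Tensor(out_data, True, (a, b), bwd)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)
    if not t.requires_grad:
        return Tensor(out_data)

    def bwd(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        return (out_data * (g - dot),)

    return Tensor(out_data, True, (t,), bwd)
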