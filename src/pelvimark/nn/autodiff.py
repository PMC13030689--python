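"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ndarray and records the operation that produced
it; calling :meth:`Tensor.backward` on a scalar result accumulates gradients
into every reachable leaf with ``requires_grad=True``.  Only the primitives
the point-cloud networks need are provided (dense linear algebra, pointwise
nonlinearities, gathers/reductions, a 3x3 inverse for the polar-decomposition
rotation projection, and the trig inverses used by the Euler-angle loss).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "maximum_scalar"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Undo NumPy broadcasting: reduce ``grad`` back to ``shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(value, parents, backward) -> "Tensor":
        out = Tensor(value)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.value.shape

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            return (_sum_to_shape(g, a.shape), _sum_to_shape(g, b.shape))

        return Tensor._make(a.value + b.value, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.value, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            return (
                _sum_to_shape(g * b.value, a.shape),
                _sum_to_shape(g * a.value, b.shape),
            )

        return Tensor._make(a.value * b.value, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            return (
                _sum_to_shape(g / b.value, a.shape),
                _sum_to_shape(-g * a.value / b.value**2, b.shape),
            )

        return Tensor._make(a.value / b.value, (a, b), bw)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            ga = g @ np.swapaxes(b.value, -1, -2)
            gb = np.swapaxes(a.value, -1, -2) @ g
            return (_sum_to_shape(ga, a.shape), _sum_to_shape(gb, b.shape))

        return Tensor._make(a.value @ b.value, (a, b), bw)

    def __pow__(self, p: float):
        def bw(g):
            return (g * p * self.value ** (p - 1),)

        return Tensor._make(self.value**p, (self,), bw)

    # -- shaping ---------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        return Tensor._make(
            self.value.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(
            self.value.transpose(*axes), (self,), lambda g: (g.transpose(*inv),)
        )

    def __getitem__(self, idx):
        def bw(g):
            out = np.zeros_like(self.value)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(self.value[idx], (self,), bw)

    def gather(self, index: np.ndarray, batched: bool = False) -> "Tensor":
        """Row-gather along the point axis.

        Unbatched: value (N, F), index (...,) -> (..., F).
        Batched: value (B, N, F), index (B, ...) -> (B, ..., F), each batch
        element gathered from its own row block.
        """
        if not batched:
            return self[index]
        B = self.value.shape[0]
        bidx = np.arange(B).reshape((B,) + (1,) * (index.ndim - 1))

        def bw(g):
            out = np.zeros_like(self.value)
            np.add.at(out, (bidx, index), g)
            return (out,)

        return Tensor._make(self.value[bidx, index], (self,), bw)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._make(self.value.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims=False):
        arg = self.value.argmax(axis=axis)
        val = np.take_along_axis(self.value, np.expand_dims(arg, axis), axis=axis)

        def bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            out = np.zeros_like(self.value)
            np.put_along_axis(out, np.expand_dims(arg, axis), gg, axis=axis)
            return (out,)

        res = val if keepdims else np.squeeze(val, axis=axis)
        return Tensor._make(res, (self,), bw)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.value > 0
        return Tensor._make(self.value * mask, (self,), lambda g: (g * mask,))

    def exp(self):
        out_val = np.exp(self.value)
        return Tensor._make(out_val, (self,), lambda g: (g * out_val,))

    def sqrt(self):
        out_val = np.sqrt(self.value)
        return Tensor._make(out_val, (self,), lambda g: (g * 0.5 / out_val,))

    def log_softmax(self, axis: int = -1):
        m = self.value.max(axis=axis, keepdims=True)
        z = self.value - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_val = z - lse

        def bw(g):
            return (g - np.exp(out_val) * g.sum(axis=axis, keepdims=True),)

        return Tensor._make(out_val, (self,), bw)

    def arcsin(self):
        def bw(g):
            return (g / np.sqrt(np.maximum(1.0 - self.value**2, 1e-12)),)

        return Tensor._make(np.arcsin(np.clip(self.value, -1.0, 1.0)), (self,), bw)

    def clip(self, lo: float, hi: float):
        mask = (self.value > lo) & (self.value < hi)
        return Tensor._make(
            np.clip(self.value, lo, hi), (self,), lambda g: (g * mask,)
        )

    def inv3(self):
        """Batched inverse of (..., 3, 3) matrices."""
        inv_val = np.linalg.inv(self.value)

        def bw(g):
            it = np.swapaxes(inv_val, -1, -2)
            return (-it @ g @ it,)

        return Tensor._make(inv_val, (self,), bw)

    # -- backprop ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def atan2(y: Tensor, x: Tensor) -> Tensor:
    y, x = Tensor._lift(y), Tensor._lift(x)

    def bw(g):
        denom = x.value**2 + y.value**2
        return (
            _sum_to_shape(g * x.value / denom, y.shape),
            _sum_to_shape(-g * y.value / denom, x.shape),
        )

    return Tensor._make(np.arctan2(y.value, x.value), (y, x), bw)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.value for t in tensors], axis=axis), tensors, bw
    )


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]

    def bw(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._make(np.stack([t.value for t in tensors], axis=axis), tensors, bw)


def maximum_scalar(t: Tensor, floor: float) -> Tensor:
    mask = t.value > floor
    return Tensor._make(np.maximum(t.value, floor), (t,), lambda g: (g * mask,))
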