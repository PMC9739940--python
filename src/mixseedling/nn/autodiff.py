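"""Tape-based reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ndarray; operations record their parents
and a backward closure, and :meth:`Tensor.backward` walks the tape in reverse
topological order.  Broadcasting follows numpy semantics, with gradients
summed back over broadcast axes.  The op set is deliberately small: exactly
what the point-mixer network and its losses require.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "Tensor",
    "matmul",
    "concat",
    "take",
    "max_axis",
    "mean_axis",
    "sum_axis",
    "leaky_relu",
    "relu",
    "log_softmax",
    "sqrt",
]

ArrayLike = Union["Tensor", np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node of the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: Optional[np.ndarray] = None
        self._parents: tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], Sequence[Optional[np.ndarray]]]] = None

    # -- tape plumbing ------------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- conveniences -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: ArrayLike) -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data + other.data
        return Tensor._make(
            out_data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other: ArrayLike) -> "Tensor":
        other = _as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        other = _as_tensor(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __matmul__(self, other: "Tensor") -> "Tensor":
        return matmul(self, other)

    def reshape(self, *shape: int) -> "Tensor":
        old = self.shape
        return Tensor._make(self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),))

    def transpose(self, *axes: int) -> "Tensor":
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),))

    @property
    def T(self) -> "Tensor":
        return self.transpose()


def _as_tensor(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- functional ops ---------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with numpy batching; gradients sum over broadcast dims."""
    out = a.data @ b.data

    def backward(g: np.ndarray):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return Tensor._make(out, (a, b), backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def take(t: Tensor, index: np.ndarray) -> Tensor:
    """Gather rows along axis 0 by an arbitrary-shape integer index; the
    gradient scatter-adds into the source rows."""
    index = np.asarray(index)

    def backward(g: np.ndarray):
        out = np.zeros_like(t.data)
        np.add.at(out, index, g)
        return (out,)

    return Tensor._make(t.data[index], (t,), backward)


def max_axis(t: Tensor, axis: int) -> Tensor:
    """Max over one axis; the gradient routes to the first argmax."""
    idx = np.argmax(t.data, axis=axis)
    out = np.take_along_axis(t.data, np.expand_dims(idx, axis), axis=axis).squeeze(axis)

    def backward(g: np.ndarray):
        gi = np.zeros_like(t.data)
        np.put_along_axis(gi, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis)
        return (gi,)

    return Tensor._make(out, (t,), backward)


def sum_axis(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def backward(g: np.ndarray):
        if axis is None:
            return (np.broadcast_to(g, t.shape).copy(),)
        gg = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(gg, t.shape).copy(),)

    return Tensor._make(t.data.sum(axis=axis, keepdims=keepdims), (t,), backward)


def mean_axis(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    count = t.data.size if axis is None else t.data.shape[axis]
    return sum_axis(t, axis=axis, keepdims=keepdims) * (1.0 / count)


def leaky_relu(t: Tensor, negative_slope: float = 0.01) -> Tensor:
    slope = np.where(t.data > 0, 1.0, negative_slope)
    return Tensor._make(t.data * slope, (t,), lambda g: (g * slope,))


def relu(t: Tensor) -> Tensor:
    mask = t.data > 0
    return Tensor._make(t.data * mask, (t,), lambda g: (g * mask,))


def sqrt(t: Tensor) -> Tensor:
    out = np.sqrt(t.data)

    def backward(g: np.ndarray):
        return (g * 0.5 / np.maximum(out, 1e-12),)

    return Tensor._make(out, (t,), backward)


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax along ``axis``."""
    m = t.data.max(axis=axis, keepdims=True)
    shifted = t.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - lse
    softmax = np.exp(out)

    def backward(g: np.ndarray):
        return (g - softmax * g.sum(axis=axis, keepdims=True),)

    return Tensor._make(out, (t,), backward)
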