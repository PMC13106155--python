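"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine: every operation returns a new :class:`Tensor`
holding references to its parents together with closures that map the
output gradient to each parent's gradient contribution.  ``backward()``
runs a topological sweep.  All data is float64; broadcasting follows
numpy semantics, with gradients summed over broadcast axes.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "concat",
    "matmul",
    "softmax",
    "log_softmax",
    "sigmoid",
    "clip",
    "relu6",
    "h_sigmoid_t",
    "h_swish_t",
    "gelu",
    "take",
    "roll",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """N-d array with optional gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence[tuple["Tensor", Callable[[np.ndarray], np.ndarray]]] = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        # parents kept only while they matter for backprop
        self._parents = tuple(p for p in parents if p[0].requires_grad)

    # ------------------------------------------------------------------ misc
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for parent, fn in node._parents:
                contribution = fn(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + contribution
                else:
                    grads[id(parent)] = contribution

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=((self, lambda g: _unbroadcast(g, self.shape)),
                              (other, lambda g: _unbroadcast(g, other.shape))))
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, self.requires_grad, ((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor(a.data * b.data,
                      requires_grad=a.requires_grad or b.requires_grad,
                      parents=((a, lambda g: _unbroadcast(g * b.data, a.shape)),
                               (b, lambda g: _unbroadcast(g * a.data, b.shape))))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor(a.data / b.data,
                      requires_grad=a.requires_grad or b.requires_grad,
                      parents=((a, lambda g: _unbroadcast(g / b.data, a.shape)),
                               (b, lambda g: _unbroadcast(-g * a.data / (b.data ** 2), b.shape))))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent
        return Tensor(out_data, self.requires_grad,
                      ((self, lambda g: g * exponent * self.data ** (exponent - 1)),))

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape
        return Tensor(self.data.reshape(shape), self.requires_grad,
                      ((self, lambda g: g.reshape(old_shape)),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = tuple(np.argsort(axes))
        return Tensor(self.data.transpose(axes), self.requires_grad,
                      ((self, lambda g: g.transpose(inverse)),))

    def __getitem__(self, key):
        def grad_fn(g, key=key, shape=self.shape):
            out = np.zeros(shape, dtype=np.float64)
            np.add.at(out, key, g)
            return out

        return Tensor(self.data[key], self.requires_grad, ((self, grad_fn),))

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g, axis=axis, keepdims=keepdims, shape=self.shape):
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, shape).copy()

        return Tensor(out_data, self.requires_grad, ((self, grad_fn),))

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor(out_data, self.requires_grad, ((self, lambda g: g * out_data),))

    def log(self):
        return Tensor(np.log(self.data), self.requires_grad,
                      ((self, lambda g: g / self.data),))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor(out_data, self.requires_grad,
                      ((self, lambda g: g * 0.5 / out_data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor(out_data, self.requires_grad,
                      ((self, lambda g: g * (1.0 - out_data ** 2)),))


class Parameter(Tensor):
    """A tensor that is optimized during training."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


# ------------------------------------------------------------------ functions
def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def grad_a(g):
        bd = b.data
        if bd.ndim == 1:
            res = np.expand_dims(g, -1) * bd
        else:
            res = g @ np.swapaxes(bd, -1, -2)
        return _unbroadcast(res, a.shape)

    def grad_b(g):
        ad = a.data
        if ad.ndim == 1:
            res = np.expand_dims(ad, -1) * np.expand_dims(g, -2)
        else:
            res = np.swapaxes(ad, -1, -2) @ g
        return _unbroadcast(res, b.shape)

    return Tensor(out_data, a.requires_grad or b.requires_grad,
                  ((a, grad_a), (b, grad_b)))


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    offset = 0
    for t in tensors:
        width = t.shape[axis]

        def grad_fn(g, start=offset, stop=offset + width, axis=axis):
            index = [slice(None)] * g.ndim
            index[axis] = slice(start, stop)
            return g[tuple(index)]

        parents.append((t, grad_fn))
        offset += width
    return Tensor(out_data, any(t.requires_grad for t in tensors), parents)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    x = as_tensor(x)
    mask = (x.data > lo) & (x.data < hi)
    return Tensor(np.clip(x.data, lo, hi), x.requires_grad,
                  ((x, lambda g: g * mask),))


def relu6(x: Tensor) -> Tensor:
    return clip(x, 0.0, 6.0)


def h_sigmoid_t(x: Tensor) -> Tensor:
    """Hard sigmoid, ReLU6(x + 3) / 6, on tensors."""
    return relu6(as_tensor(x) + 3.0) * (1.0 / 6.0)


def h_swish_t(x: Tensor) -> Tensor:
    """Hard swish, x * h_sigmoid(x), on tensors."""
    x = as_tensor(x)
    return x * h_sigmoid_t(x)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(out_data, x.requires_grad,
                  ((x, lambda g: g * out_data * (1.0 - out_data)),))


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (exact erf form)."""
    x = as_tensor(x)
    phi = 0.5 * (1.0 + _erf(x.data / np.sqrt(2.0)))
    density = np.exp(-0.5 * x.data ** 2) / np.sqrt(2.0 * np.pi)
    return Tensor(x.data * phi, x.requires_grad,
                  ((x, lambda g: g * (phi + x.data * density)),))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def take(x: Tensor, indices: np.ndarray, axis: int = 0) -> Tensor:
    """Integer-array gather along ``axis`` with scatter-add gradient."""
    x = as_tensor(x)
    indices = np.asarray(indices)
    out_data = np.take(x.data, indices, axis=axis)

    def grad_fn(g, axis=axis, shape=x.shape):
        out = np.zeros(shape, dtype=np.float64)
        moved = np.moveaxis(out, axis, 0)
        g_moved = np.moveaxis(g, tuple(range(axis, axis + indices.ndim)),
                              tuple(range(indices.ndim)))
        np.add.at(moved, indices, g_moved)
        return out

    return Tensor(out_data, x.requires_grad, ((x, grad_fn),))


def roll(x: Tensor, shift, axis) -> Tensor:
    x = as_tensor(x)
    neg = tuple(-s for s in shift) if isinstance(shift, tuple) else -shift
    return Tensor(np.roll(x.data, shift, axis), x.requires_grad,
                  ((x, lambda g: np.roll(g, neg, axis)),))
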