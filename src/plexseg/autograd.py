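"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine: every operation builds a node holding its parents
and a closure that maps the output gradient to parent gradients.  Calling
:meth:`Tensor.backward` on a scalar runs the tape in reverse topological
order.  All data is float64 so that finite-difference gradient checks are
meaningful at tight tolerances.

Only the operations the segmentation model needs are provided; shapes follow
NumPy broadcasting, and gradients of broadcast operands are summed back to
the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concatenate", "stack", "where_mask", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over dimensions that were broadcast up from `shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra dims
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative post-order DFS (graphs can be deep)
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.append(node)
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if pgrad is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.array(pgrad, dtype=np.float64)
                else:
                    parent.grad = parent.grad + pgrad

    # ------------------------------------------------------------- op helpers
    @staticmethod
    def _make(data, parents, backward):
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            return Tensor(data, requires_grad=True, _parents=tuple(parents), _backward=backward)
        return Tensor(data)

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._coerce(other)
        out = self.data + other.data
        return Tensor._make(out, (self, other), lambda g: (
            _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = self._coerce(other)
        out = self.data - other.data
        return Tensor._make(out, (self, other), lambda g: (
            _unbroadcast(g, self.data.shape), _unbroadcast(-g, other.data.shape)))

    def __rsub__(self, other):
        return self._coerce(other) - self

    def __mul__(self, other):
        other = self._coerce(other)
        out = self.data * other.data
        return Tensor._make(out, (self, other), lambda g: (
            _unbroadcast(g * other.data, self.data.shape),
            _unbroadcast(g * self.data, other.data.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = self.data / other.data
        return Tensor._make(out, (self, other), lambda g: (
            _unbroadcast(g / other.data, self.data.shape),
            _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)))

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        out = self.data ** p
        return Tensor._make(out, (self,), lambda g: (g * p * self.data ** (p - 1),))

    def __matmul__(self, other):
        other = self._coerce(other)
        out = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                return g * b, g * a
            if a.ndim == 1:  # (k,) @ (..,k,n)
                ga = _unbroadcast((g[..., None, :] * b).sum(-1), a.shape)
                gb = _unbroadcast(a[:, None] * g[..., None, :], b.shape)
                return ga, gb
            if b.ndim == 1:  # (..,m,k) @ (k,)
                ga = _unbroadcast(g[..., :, None] * b, a.shape)
                gb = _unbroadcast((a * g[..., :, None]).sum(tuple(range(a.ndim - 1))), b.shape)
                return ga, gb
            ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
            gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return ga, gb

        return Tensor._make(out, (self, other), backward)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), lambda g: (g / (2.0 * out),))

    def abs(self):
        return Tensor._make(np.abs(self.data), (self,), lambda g: (g * np.sign(self.data),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, (self,), lambda g: (g * (1.0 - out ** 2),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def gelu(self):
        # tanh approximation; smooth and cheap, derivative in closed form
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
            return (g * d,)

        return Tensor._make(out, (self,), backward)

    def maximum(self, other):
        other = self._coerce(other)
        out = np.maximum(self.data, other.data)
        mask = self.data >= other.data
        return Tensor._make(out, (self, other), lambda g: (
            _unbroadcast(g * mask, self.data.shape),
            _unbroadcast(g * ~mask, other.data.shape)))

    def minimum(self, other):
        other = self._coerce(other)
        out = np.minimum(self.data, other.data)
        mask = self.data <= other.data
        return Tensor._make(out, (self, other), lambda g: (
            _unbroadcast(g * mask, self.data.shape),
            _unbroadcast(g * ~mask, other.data.shape)))

    def clamp(self, lo=None, hi=None):
        out = np.clip(self.data, lo, hi)
        inside = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            inside &= self.data >= lo
        if hi is not None:
            inside &= self.data <= hi
        return Tensor._make(out, (self,), lambda g: (g * inside,))

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Tensor._make(out, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        out = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            full = self.data.max(axis=axis, keepdims=True)
            mask = self.data == full
            mask = mask / mask.sum(axis=axis, keepdims=True)
            gg = g if (keepdims or axis is None) else np.expand_dims(g, axis)
            return (mask * gg,)

        return Tensor._make(out, (self,), backward)

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            return (out * (g - dot),)

        return Tensor._make(out, (self,), backward)

    def log_softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse
        soft = np.exp(out)

        def backward(g):
            return (g - soft * g.sum(axis=axis, keepdims=True),)

        return Tensor._make(out, (self,), backward)

    # ------------------------------------------------------------- structure
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(self.data.reshape(shape), (self,), lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),))

    @property
    def T(self):
        return self.transpose(*reversed(range(self.data.ndim)))

    def __getitem__(self, idx):
        out = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(out, (self,), backward)

    def roll(self, shift, axis):
        return Tensor._make(np.roll(self.data, shift, axis=axis), (self,),
                            lambda g: (np.roll(g, tuple(-s for s in shift) if isinstance(shift, tuple) else -shift,
                                               axis=axis),))

    def pad2d(self, pad_h: int, pad_w: int, mode: str = "constant"):
        """Pad the last two axes."""
        width = [(0, 0)] * (self.data.ndim - 2) + [(0, pad_h), (0, pad_w)]
        out = np.pad(self.data, width, mode=mode)
        H, W = self.data.shape[-2], self.data.shape[-1]

        def backward(g):
            if mode == "constant":
                return (g[..., :H, :W].copy(),)
            raise NotImplementedError("gradient only for constant padding")

        return Tensor._make(out, (self,), backward)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out, tuple(tensors), backward)


def stack(tensors, axis=0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        moved = np.moveaxis(g, axis, 0)
        return tuple(moved[i] for i in range(len(tensors)))

    return Tensor._make(out, tuple(tensors), backward)


def where_mask(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select a where boolean `mask` is true else b; mask carries no gradient."""
    a, b = Tensor._coerce(a), Tensor._coerce(b)
    out = np.where(mask, a.data, b.data)
    return Tensor._make(out, (a, b), lambda g: (
        _unbroadcast(g * mask, a.data.shape), _unbroadcast(g * ~mask, b.data.shape)))
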