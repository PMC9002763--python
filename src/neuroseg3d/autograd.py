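"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation network in this package runs on plain numpy (BLAS-backed
matmuls, float32 by default). This module provides the small tensor/tape
abstraction the model and training loop are built on: a :class:`Tensor`
wrapping an ndarray, a set of differentiable primitives with numpy
broadcasting semantics, and :meth:`Tensor.backward` performing reverse-mode
accumulation over a topologically sorted tape.

Only the operations the architecture needs are implemented (elementwise
arithmetic, matmul with batch broadcasting, reductions, exp/log/sqrt, ReLU,
reshape/transpose/concatenate, clipping). Convolution and upsampling live in
:mod:`neuroseg3d.model` as custom primitives built with :func:`make_op`.

The free functions (:func:`log`, :func:`exp`, ...) dispatch on type: given a
Tensor they build graph nodes, given an ndarray they call numpy directly.
This lets the loss functions in :mod:`neuroseg3d.losses` be written once and
serve both as plain evaluators and as differentiable training objectives.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "make_op",
    "concatenate",
    "exp",
    "log",
    "sqrt",
    "relu",
    "clip",
    "softmax",
    "where_max_shift",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were expanded
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={'yes' if self.requires_grad else 'no'})"

    # -- graph construction -------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode accumulation from this (typically scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, like=self)
        out = _node(self.data + other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other, like=self)
        out = _node(self.data * other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other, like=self))

    def __rsub__(self, other):
        return as_tensor(other, like=self) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other, like=self)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) * self ** -1.0

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("only constant exponents are supported")
        out = _node(self.data ** exponent, (self,))
        if out.requires_grad:
            def bwd(g):
                if exponent == 0:
                    return  # constant output, zero gradient
                with np.errstate(divide="ignore", invalid="ignore"):
                    d = exponent * self.data ** (exponent - 1.0)
                # subgradient choice 0 where x**(e-1) blows up at x = 0
                d = np.where(np.isfinite(d), d, 0.0).astype(self.data.dtype)
                self._accumulate(g * d)
            out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other, like=self)
        out = _node(self.data @ other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accumulate(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accumulate(_unbroadcast(gb, other.shape))
            out._backward = bwd
        return out

    def __rmatmul__(self, other):
        return as_tensor(other, like=self) @ self

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bwd(g):
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, axes)
                self._accumulate(np.broadcast_to(g, self.shape))
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation ---------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = tuple(np.argsort(axes))
        out = _node(self.data.transpose(axes), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.transpose(inverse))
        return out


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(p for p in parents if p.requires_grad))


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None and np.issubdtype(like.dtype, np.floating) else None
    return Tensor(np.asarray(x, dtype=dtype))


def make_op(forward, backward, *parents: Tensor) -> Tensor:
    """Build a custom primitive.

    `forward()` returns the output ndarray; `backward(g)` returns one gradient
    ndarray per parent (or None for parents not requiring grad).
    """
    out = _node(forward(), tuple(parents))
    if out.requires_grad:
        def bwd(g):
            grads = backward(g)
            for p, gp in zip(parents, grads):
                if p.requires_grad and gp is not None:
                    p._accumulate(gp)
        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# free functions, dispatching on Tensor vs ndarray
# ---------------------------------------------------------------------------

def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def exp(x):
    if not _is_tensor(x):
        return np.exp(x)
    out = _node(np.exp(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g * out.data)
    return out


def log(x):
    if not _is_tensor(x):
        return np.log(x)
    out = _node(np.log(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g / x.data)
    return out


def sqrt(x):
    if not _is_tensor(x):
        return np.sqrt(x)
    return x ** 0.5


def relu(x):
    if not _is_tensor(x):
        return np.maximum(x, 0.0)
    out = _node(np.maximum(x.data, 0.0), (x,))
    if out.requires_grad:
        mask = (x.data > 0).astype(x.data.dtype)
        out._backward = lambda g: x._accumulate(g * mask)
    return out


def clip(x, lo: float, hi: float):
    """Clip values; gradient is passed through on the interior, zero outside."""
    if not _is_tensor(x):
        return np.clip(x, lo, hi)
    out = _node(np.clip(x.data, lo, hi), (x,))
    if out.requires_grad:
        mask = ((x.data >= lo) & (x.data <= hi)).astype(x.data.dtype)
        out._backward = lambda g: x._accumulate(g * mask)
    return out


def where_max_shift(x):
    """Subtract the per-row max as a constant (softmax stabilisation)."""
    if not _is_tensor(x):
        return x - x.max(axis=-1, keepdims=True)
    shift = x.data.max(axis=-1, keepdims=True)
    return x - Tensor(shift)


def softmax(x, axis: int = -1):
    """Numerically stable softmax along `axis`."""
    if not _is_tensor(x):
        z = x - x.max(axis=axis, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=axis, keepdims=True)
    if axis not in (-1, x.ndim - 1):
        order = list(range(x.ndim))
        order[axis], order[-1] = order[-1], order[axis]
        return softmax(x.transpose(order), axis=-1).transpose(order)
    e = exp(where_max_shift(x))
    return e * e.sum(axis=-1, keepdims=True) ** -1.0


def concatenate(tensors, axis: int = 0):
    if not any(_is_tensor(t) for t in tensors):
        return np.concatenate(tensors, axis=axis)
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = bwd
    return out
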