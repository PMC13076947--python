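"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains several small coupled networks (edge-type convolutions,
graph convolutions, attention pooling, fusion perceptrons) end-to-end with a
mean-squared-error loss.  This module provides the tape: a :class:`Tensor`
wraps an ``ndarray``, records the operations applied to it, and
:meth:`Tensor.backward` accumulates gradients by walking the tape in reverse
topological order.  Everything runs in float64, which is what makes the
finite-difference gradient checks in the test-suite meaningful at relative
errors of 1e-4 and below.

Only the operations the model needs are implemented: elementwise arithmetic
with numpy broadcasting, matrix multiplication, a few nonlinearities,
reductions, concatenation and row gathering.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "relu", "tanh", "softmax", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # defer mixed ndarray-Tensor arithmetic to the reflected Tensor ops
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        out_data = a @ b

        def backward(g):
            if a.ndim == 2 and b.ndim == 2:
                return (g @ b.T, a.T @ g)
            if a.ndim == 2 and b.ndim == 1:  # (n,k)@(k,) -> (n,)
                return (np.outer(g, b), a.T @ g)
            if a.ndim == 1 and b.ndim == 2:  # (k,)@(k,m) -> (m,)
                return (b @ g, np.outer(a, g))
            return (g * b, g * a)  # (k,)@(k,) -> scalar

        return Tensor._make(out_data, (self, other), backward)

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # -- reductions and reshaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward(g):
            return (g.reshape(self.shape),)

        return Tensor._make(out_data, (self,), backward)

    @property
    def T(self):
        out_data = self.data.T

        def backward(g):
            return (g.T,)

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(out_data, (self,), backward)

    # -- nonlinearities ---------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor._make(t, (self,), lambda g: (g * (1.0 - t**2),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor._make(e, (self,), lambda g: (g * e,))

    def sqrt(self):
        return self**0.5

    def abs(self):
        s = np.sign(self.data)
        return Tensor._make(np.abs(self.data), (self,), lambda g: (g * s,))

    # -- backward pass ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; tapes can exceed the recursion limit
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad = parent.grad + g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- functional helpers that accept either Tensor or ndarray ---------------------


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def relu(x):
    return x.relu() if isinstance(x, Tensor) else np.maximum(x, 0.0)


def tanh(x):
    return x.tanh() if isinstance(x, Tensor) else np.tanh(x)


def softmax(x, axis: int = -1):
    """Numerically stable softmax along ``axis`` for arrays or Tensors."""
    if isinstance(x, Tensor):
        shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
        e = (x - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)
    x = np.asarray(x, dtype=np.float64)
    e = np.exp(x - np.max(x, axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def concat(parts, axis: int = -1):
    if not _is_tensor(*parts):
        return np.concatenate(parts, axis=axis)
    parts = [as_tensor(p) for p in parts]
    out_data = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, parts, backward)


def stack_rows(parts):
    """Stack 1-D pieces into a 2-D array/Tensor (row per piece)."""
    if not _is_tensor(*parts):
        return np.stack(parts, axis=0)
    parts = [as_tensor(p) for p in parts]
    out_data = np.stack([p.data for p in parts], axis=0)

    def backward(g):
        return tuple(g[i] for i in range(len(parts)))

    return Tensor._make(out_data, parts, backward)
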