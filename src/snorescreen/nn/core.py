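"""A small reverse-mode autodiff core over numpy arrays.

Provides exactly the primitives the snore classifier needs: broadcasting
elementwise arithmetic, (batched) matmul, the usual activations, reductions,
shape ops, and hand-written efficient forward/backward kernels for 2-D
convolution, batch normalization and max pooling.  Gradients are plain
numpy arrays accumulated on leaf tensors.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
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
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
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
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad)
        ).astype(self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None  # free closures/saved activations

    # -- helpers -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- elementwise arithmetic --------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            a._accumulate(_unbroadcast(g, a.data.shape))
            b._accumulate(_unbroadcast(g, b.data.shape))

        return self._node(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return self._node(-a.data, (a,), lambda g: a._accumulate(-g))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return self._node(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

        return self._node(a.data / b.data, (a, b), bw)

    # -- matmul ------------------------------------------------------------

    def matmul(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            a._accumulate(
                _unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)), a.data.shape)
            )
            b._accumulate(
                _unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g), b.data.shape)
            )

        return self._node(np.matmul(a.data, b.data), (a, b), bw)

    __matmul__ = matmul

    # -- activations -------------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0
        return self._node(a.data * mask, (a,), lambda g: a._accumulate(g * mask))

    def sigmoid(self):
        a = self
        y = 1.0 / (1.0 + np.exp(-a.data))
        return self._node(y, (a,), lambda g: a._accumulate(g * y * (1.0 - y)))

    def tanh(self):
        a = self
        y = np.tanh(a.data)
        return self._node(y, (a,), lambda g: a._accumulate(g * (1.0 - y**2)))

    def exp(self):
        a = self
        y = np.exp(a.data)
        return self._node(y, (a,), lambda g: a._accumulate(g * y))

    def log(self):
        a = self
        return self._node(np.log(a.data), (a,), lambda g: a._accumulate(g / a.data))

    # -- reductions and shape ops ------------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self
        y = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return self._node(y, (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = a.data.shape
        return self._node(
            a.data.reshape(shape), (a,), lambda g: a._accumulate(g.reshape(old))
        )

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return self._node(
            a.data.transpose(axes), (a,), lambda g: a._accumulate(g.transpose(inv))
        )

    def take_time(self, t: int, axis: int = 1):
        """Select one index along ``axis`` (used to step through sequences)."""
        a = self
        idx = [slice(None)] * a.data.ndim
        idx[axis] = t
        idx = tuple(idx)

        def bw(g):
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accumulate(full)

        return self._node(a.data[idx], (a,), bw)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )
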