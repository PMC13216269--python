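"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine in the spirit of micrograd, but vectorized:
:class:`Tensor` wraps an ``ndarray``, records the operations applied to it,
and :meth:`Tensor.backward` accumulates gradients by walking the tape in
reverse topological order.  Only the operations the package's models need
are provided (broadcast arithmetic, matmul, reductions, unfold for
convolution, indexing, concatenation); each op's gradient is exercised by
finite-difference tests.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "astensor", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self._grad_borrowed = False

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        # first contribution is borrowed (possibly a view into a child's
        # grad); it is never mutated in place — a second contribution
        # replaces it with a fresh sum
        if self.grad is None:
            self.grad = g
            self._grad_borrowed = True
        elif self._grad_borrowed:
            self.grad = self.grad + g
            self._grad_borrowed = False
        else:
            self.grad += g

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = astensor(other)
        out_data = self.data + other.data

        def backward(g):
            yield self, _unbroadcast(g, self.shape)
            yield other, _unbroadcast(g, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            yield self, -g

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                yield self, _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                yield other, _unbroadcast(g * self.data, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                yield self, _unbroadcast(g / other.data, self.shape)
            if other.requires_grad:
                yield other, _unbroadcast(-g * self.data / other.data**2, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def backward(g):
            yield self, g * exponent * self.data ** (exponent - 1)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = astensor(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                if self.requires_grad:
                    yield self, g * b
                if other.requires_grad:
                    yield other, g * a
                return
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(b, -1, -2)) if b.ndim > 1 \
                    else np.multiply.outer(g, b)
                yield self, _unbroadcast(ga, self.shape)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(a, -1, -2), g) if a.ndim > 1 \
                    else np.multiply.outer(a, g)
                yield other, _unbroadcast(gb, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise functions -------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            yield self, g * out_data

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            yield self, g / self.data

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            yield self, g * 0.5 / out_data

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            yield self, g * (1.0 - out_data**2)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            yield self, g * mask

        return Tensor._make(self.data * mask, (self,), backward)

    # -- reductions ------------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                yield self, np.broadcast_to(g, self.shape).copy()
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                yield self, np.broadcast_to(gg, self.shape).copy()

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis=None, keepdims: bool = False):
        """Max reduction; gradient flows to the (first) argmax entries."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            expanded = out_data if keepdims or axis is None else np.expand_dims(out_data, axis)
            mask = self.data == expanded
            # split ties evenly so the gradient check is symmetric
            denom = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            gg = g if keepdims or axis is None else np.expand_dims(g, axis)
            yield self, mask * gg / denom

        return Tensor._make(out_data, (self,), backward)

    # -- shape manipulation -----------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            yield self, g.reshape(old)

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = tuple(np.argsort(axes))

        def backward(g):
            yield self, g.transpose(inv)

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            yield self, full

        return Tensor._make(out_data, (self,), backward)

    def pad2d(self, ph: int, pw: int):
        """Zero-pad the last two axes symmetrically."""
        if ph == 0 and pw == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(ph, ph), (pw, pw)]
        out_data = np.pad(self.data, width)
        sl = (Ellipsis, slice(ph, self.shape[-2] + ph), slice(pw, self.shape[-1] + pw))

        def backward(g):
            yield self, g[sl]

        return Tensor._make(out_data, (self,), backward)

    def unfold2d(self, kh: int, kw: int, stride: int = 1):
        """Extract sliding ``kh x kw`` patches from a (..., H, W) tensor.

        Returns a tensor of shape (..., H', W', kh, kw) with
        H' = (H - kh)//stride + 1.  The backward pass scatter-adds patch
        gradients back into place with kh*kw vectorized slice additions.
        """
        windows = np.lib.stride_tricks.sliding_window_view(self.data, (kh, kw), axis=(-2, -1))
        out_data = np.ascontiguousarray(windows[..., ::stride, ::stride, :, :])
        H, W = self.shape[-2], self.shape[-1]
        Ho = (H - kh) // stride + 1
        Wo = (W - kw) // stride + 1

        def backward(g):
            full = np.zeros_like(self.data)
            for i in range(kh):
                for j in range(kw):
                    full[..., i : i + (Ho - 1) * stride + 1 : stride,
                         j : j + (Wo - 1) * stride + 1 : stride] += g[..., :, :, i, j]
            yield self, full

        return Tensor._make(out_data, (self,), backward)

    # -- autodiff driver ---------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))

        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in node._backward(node.grad):
                if parent.requires_grad:
                    parent._accumulate(g)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            yield t, g[tuple(sl)]

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            yield t, np.take(g, i, axis=axis)

    return Tensor._make(out_data, tuple(tensors), backward)
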