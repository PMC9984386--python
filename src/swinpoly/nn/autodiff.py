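"""Minimal vectorized reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` replays the tape in reverse topological
order accumulating gradients.  The op set is exactly what a windowed-attention
transformer needs: broadcasting arithmetic, batched ``matmul``, shape
manipulation (reshape / transpose / roll / concatenate / indexing), stable
``softmax`` / ``log_softmax``, layer normalization, GELU, and an embedding
``take`` with scatter-add backward for relative-position-bias tables.

Everything runs in float32 by default; float64 is supported for
finite-difference gradient checks.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast so it matches `shape`."""
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
    """An ndarray plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- tape plumbing -------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[["Tensor"], None] | None) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep tapes exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)
        out = self._make(self.data + other.data, (self, other), None)

        def bw(o: Tensor) -> None:
            self._accum(_unbroadcast(o.grad, self.shape))
            other._accum(_unbroadcast(o.grad, other.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = self._make(-self.data, (self,), None)
        out._backward = (lambda o: self._accum(-o.grad)) if out.requires_grad else None
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)
        out = self._make(self.data * other.data, (self, other), None)

        def bw(o: Tensor) -> None:
            self._accum(_unbroadcast(o.grad * other.data, self.shape))
            other._accum(_unbroadcast(o.grad * self.data, other.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._coerce(other)
        out = self._make(self.data / other.data, (self, other), None)

        def bw(o: Tensor) -> None:
            self._accum(_unbroadcast(o.grad / other.data, self.shape))
            other._accum(_unbroadcast(-o.grad * self.data / other.data ** 2, other.shape))

        out._backward = bw if out.requires_grad else None
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        out = self._make(self.data ** exponent, (self,), None)

        def bw(o: Tensor) -> None:
            self._accum(o.grad * exponent * self.data ** (exponent - 1))

        out._backward = bw if out.requires_grad else None
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._coerce(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def bw(o: Tensor) -> None:
            self._accum(_unbroadcast(o.grad @ np.swapaxes(other.data, -1, -2), self.shape))
            other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ o.grad, other.shape))

        out._backward = bw if out.requires_grad else None
        return out

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,), None)
        out._backward = (lambda o: self._accum(o.grad.reshape(self.shape))) \
            if out.requires_grad else None
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        out = self._make(self.data.transpose(axes), (self,), None)
        out._backward = (lambda o: self._accum(o.grad.transpose(inv))) \
            if out.requires_grad else None
        return out

    def roll(self, shift: tuple[int, ...], axis: tuple[int, ...]) -> "Tensor":
        out = self._make(np.roll(self.data, shift, axis=axis), (self,), None)
        neg = tuple(-s for s in shift)
        out._backward = (lambda o: self._accum(np.roll(o.grad, neg, axis=axis))) \
            if out.requires_grad else None
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = self._make(self.data[idx], (self,), None)

        def bw(o: Tensor) -> None:
            g = np.zeros_like(self.data)
            np.add.at(g, idx, o.grad)
            self._accum(g)

        out._backward = bw if out.requires_grad else None
        return out

    def take(self, indices: np.ndarray) -> "Tensor":
        """Embedding-style lookup along axis 0 with scatter-add backward."""
        out = self._make(self.data[indices], (self,), None)

        def bw(o: Tensor) -> None:
            g = np.zeros_like(self.data)
            np.add.at(g, indices, o.grad)
            self._accum(g)

        out._backward = bw if out.requires_grad else None
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bw(o: Tensor) -> None:
            g = o.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self) -> "Tensor":
        out = self._make(np.exp(self.data), (self,), None)
        out._backward = (lambda o: self._accum(o.grad * o.data)) \
            if out.requires_grad else None
        return out

    def log(self) -> "Tensor":
        out = self._make(np.log(self.data), (self,), None)
        out._backward = (lambda o: self._accum(o.grad / self.data)) \
            if out.requires_grad else None
        return out

    def relu(self) -> "Tensor":
        out = self._make(np.maximum(self.data, 0), (self,), None)
        out._backward = (lambda o: self._accum(o.grad * (self.data > 0))) \
            if out.requires_grad else None
        return out

    def gelu(self) -> "Tensor":
        """Exact Gaussian-error-linear unit, 0.5·x·(1+erf(x/√2))."""
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = self._make(x * cdf, (self,), None)

        def bw(o: Tensor) -> None:
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            self._accum(o.grad * (cdf + x * pdf))

        out._backward = bw if out.requires_grad else None
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = self._make(s, (self,), None)

        def bw(o: Tensor) -> None:
            g = o.grad
            self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        out._backward = bw if out.requires_grad else None
        return out

    def log_softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = self._make(ls, (self,), None)

        def bw(o: Tensor) -> None:
            g = o.grad
            self._accum(g - np.exp(ls) * g.sum(axis=axis, keepdims=True))

        out._backward = bw if out.requires_grad else None
        return out

    def layer_norm(self, weight: "Tensor", bias: "Tensor",
                   eps: float = 1e-5) -> "Tensor":
        """Normalize over the last axis, then scale and shift."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = self._make(xhat * weight.data + bias.data, (self, weight, bias), None)
        n = x.shape[-1]

        def bw(o: Tensor) -> None:
            g = o.grad
            weight._accum(_unbroadcast(g * xhat, weight.shape))
            bias._accum(_unbroadcast(g, bias.shape))
            gx = g * weight.data
            self._accum(inv * (gx - gx.mean(axis=-1, keepdims=True)
                               - xhat * (gx * xhat).mean(axis=-1, keepdims=True)))

        out._backward = bw if out.requires_grad else None
        return out


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        out._parents = tuple(tensors)

        def bw(o: Tensor) -> None:
            for t, g in zip(tensors, np.split(o.grad, splits, axis=axis)):
                t._accum(g)

        out._backward = bw
    return out
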