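"""Minimal reverse-mode automatic differentiation on numpy arrays.

The loss functions used here route gradients in non-standard ways (stop
gradients between the encoder and the codebook, a straight-through pass
around the non-differentiable nearest-neighbour quantization), so the
engine exposes :meth:`Tensor.detach` as a first-class operation and keeps
every backward rule explicit.  All data is float64; shapes follow the
(N, C, H, W) convention for image batches.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (evaluation mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- bookkeeping ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        """Value with the gradient path severed (the sg operator)."""
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)
        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), bw)

    # -- nonlinearities -------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def leaky_relu(self, slope: float = 0.1):
        """Leaky rectifier; the nonzero negative slope prevents the dead-unit
        collapse that plain ReLU stacks are prone to under large early
        gradients (a known failure mode for one-class inner encoders)."""
        mask = np.where(self.data > 0, 1.0, slope)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        # Guarded derivative: exact forward value, bounded slope at 0 so
        # zero-variance windows in SSIM do not produce infinities.
        out_data = np.sqrt(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / (2.0 * out_data + 1e-12))

        return Tensor._make(out_data, (self,), bw)

    # -- reductions / shaping -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.data.ndim for a in axes)
                shape = [1 if i in axes else s
                         for i, s in enumerate(self.data.shape)]
                g = g.reshape(shape)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._make(out_data, (self, other), bw)

    # -- convolution family ---------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2-D convolution; self (N,C,H,W), weight (F,C,k,k), bias (F,)."""
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        f, cw, k, _ = w.shape
        if cw != c:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {cw}")
        cols, ho, wo = _im2col(x, k, stride, padding)
        w2 = w.reshape(f, c * k * k)
        out = np.matmul(w2, cols).reshape(n, f, ho, wo)
        if bias is not None:
            out = out + bias.data.reshape(1, f, 1, 1)

        def bw(g):
            g2 = g.reshape(n, f, ho * wo)
            if weight.requires_grad:
                dw = np.tensordot(g2, cols, axes=([0, 2], [0, 2]))
                weight._accumulate(dw.reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                dcols = np.matmul(w2.T, g2)
                self._accumulate(_col2im(dcols, x.shape, k, stride, padding))

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, bw)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         stride: int = 1, padding: int = 0) -> "Tensor":
        """Transposed 2-D convolution; self (N,C,H,W), weight (C,F,k,k).

        Output side = (H - 1) * stride - 2 * padding + k.
        """
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        cw, f, k, _ = w.shape
        if cw != c:
            raise ValueError(f"conv_transpose2d channel mismatch: {c} vs {cw}")
        ho = (h - 1) * stride - 2 * padding + k
        wo = (wd - 1) * stride - 2 * padding + k
        x2 = x.reshape(n, c, h * wd)
        w2 = w.reshape(c, f * k * k)
        cols = np.matmul(w2.T[None], x2)
        out = _col2im(cols, (n, f, ho, wo), k, stride, padding)
        if bias is not None:
            out = out + bias.data.reshape(1, f, 1, 1)

        def bw(g):
            gcols, gh, gw = _im2col(g, k, stride, padding)  # (n, f*k*k, h*wd)
            if weight.requires_grad:
                dw = np.tensordot(x2, gcols, axes=([0, 2], [0, 2]))
                weight._accumulate(dw.reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                dx = np.matmul(w2[None], gcols)
                self._accumulate(dx.reshape(x.shape))

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, bw)

    def avg_pool2d(self) -> "Tensor":
        """2x2 average pooling with stride 2 (odd trailing row/col dropped)."""
        x = self.data
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2]
        out = xc.reshape(n, c, h2, 2, w2, 2).mean(axis=(3, 5))

        def bw(g):
            if not self.requires_grad:
                return
            gfull = np.zeros_like(x)
            gexp = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
            gfull[:, :, : 2 * h2, : 2 * w2] = gexp
            self._accumulate(gfull)

        return Tensor._make(out, (self,), bw)

    def gather_rows(self, indices: np.ndarray) -> "Tensor":
        """Row lookup e[indices] with scatter-add backward (embedding gather).

        self is (K, D); indices is any integer array; output has shape
        indices.shape + (D,).
        """
        idx = np.asarray(indices)
        out = self.data[idx]

        def bw(g):
            if self.requires_grad:
                dk = np.zeros_like(self.data)
                np.add.at(dk, idx.ravel(), g.reshape(-1, self.data.shape[1]))
                self._accumulate(dk)

        return Tensor._make(out, (self,), bw)


def _im2col(x: np.ndarray, k: int, stride: int, padding: int):
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]          # (n, c, ho, wo, k, k)
    cols = view.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, padding: int):
    """Scatter-add inverse of :func:`_im2col`."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * padding, w + 2 * padding
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        hi = i + stride * ho
        for j in range(k):
            wj = j + stride * wo
            out[:, :, i:hi:stride, j:wj:stride] += cols[:, :, i, j]
    if padding:
        out = out[:, :, padding:padding + h, padding:padding + w]
    return np.ascontiguousarray(out)
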