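"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set the restoration network and its
training objectives need: broadcasting arithmetic, elementwise
transcendentals (including ``lgamma`` for the evidential likelihood),
reductions, shape ops, 2D convolution (via ``sliding_window_view`` +
``tensordot``), separable fixed-kernel filtering (for the SSIM loss),
pixel shuffle and channel slicing.  Everything is float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, special

__all__ = ["Tensor", "conv2d", "separable_filter2d", "pixel_shuffle", "lgamma"]


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph bookkeeping -------------------------------------------------
    @classmethod
    def _node(cls, data, parents, backward):
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, float)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if not self.requires_grad:
            return
        self.grad = grad if self.grad is None else self.grad + grad

    # -- basics ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor._node(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._node(self.data ** p, (self,), backward)

    # -- elementwise ---------------------------------------------------------
    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._node(np.log(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._node(out_data, (self,), backward)

    def abs(self):
        def backward(g):
            self._accum(g * np.sign(self.data))

        return Tensor._node(np.abs(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._node(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = special.expit(self.data)

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._node(out_data, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out_data = np.logaddexp(0.0, self.data)
        sig = special.expit(self.data)

        def backward(g):
            self._accum(g * sig)

        return Tensor._node(out_data, (self,), backward)

    # -- reductions / shape ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._node(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._node(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return Tensor._node(self.data[key], (self,), backward)


def lgamma(t: Tensor) -> Tensor:
    """Log-gamma with digamma gradient."""
    t = Tensor.as_tensor(t)

    def backward(g):
        t._accum(g * special.digamma(t.data))

    return Tensor._node(special.gammaln(t.data), (t,), backward)


def _corr2d(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Valid cross-correlation of padded x (B,C,H,W) with w (O,C,kh,kw)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, w.shape[-2:], axis=(2, 3))  # B,C,Ho,Wo,kh,kw
    out = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))  # B,Ho,Wo,O
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 1) -> Tensor:
    """'Same'-padded 2D convolution (cross-correlation) for odd kernels."""
    x = Tensor.as_tensor(x)
    w = Tensor.as_tensor(w)
    kh, kw = w.shape[-2:]
    if not 0 <= pad <= kh - 1:
        raise ValueError(f"pad must lie in [0, {kh - 1}] for a {kh}x{kw} kernel")
    out_data = _corr2d(x.data, w.data, pad)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)

    def backward(g):
        g = np.ascontiguousarray(g)
        if w.requires_grad:
            xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
            win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
            # dW[o,c,i,j] = sum_{b,h,w} g[b,o,h,w] * win[b,c,h,w,i,j]
            gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))
            w._accum(gw)
        if x.requires_grad:
            # full correlation of g with the flipped, channel-swapped kernel
            w_flip = np.ascontiguousarray(w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
            x._accum(_corr2d(g, w_flip, pad=kh - 1 - pad))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._node(out_data, parents, backward)


def separable_filter2d(x: Tensor, kernel1d: np.ndarray) -> Tensor:
    """Filter the trailing two axes with a fixed separable kernel.

    Zero-padded ('constant') correlation along H then W; the adjoint is
    correlation with the reversed kernel, so gradients are exact.
    """
    x = Tensor.as_tensor(x)
    k = np.asarray(kernel1d, dtype=np.float64)

    def apply(a, kk):
        a = ndimage.correlate1d(a, kk, axis=-2, mode="constant", cval=0.0)
        return ndimage.correlate1d(a, kk, axis=-1, mode="constant", cval=0.0)

    def backward(g):
        x._accum(apply(g, k[::-1]))

    return Tensor._node(apply(x.data, k), (x,), backward)


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """Rearrange (B, C*r^2, H, W) to (B, C, H*r, W*r) (sub-pixel upsampling)."""
    x = Tensor.as_tensor(x)
    B, Cr2, H, W = x.shape
    C = Cr2 // (r * r)
    if C * r * r != Cr2:
        raise ValueError(f"channels {Cr2} not divisible by r^2={r * r}")

    out_data = (
        x.data.reshape(B, C, r, r, H, W)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(B, C, H * r, W * r)
    )

    def backward(g):
        gx = (
            g.reshape(B, C, H, r, W, r)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(B, Cr2, H, W)
        )
        x._accum(gx)

    return Tensor._node(out_data, (x,), backward)
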