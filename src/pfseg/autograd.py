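"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module supplies exactly the operator set the segmentation network needs:
2-D convolution (stride/padding/dilation), max pooling, bilinear up-sampling,
batch normalization, ReLU/sigmoid, channel concatenation, reductions for the
attention blocks, dense layers and a numerically stable binary cross-entropy
on logits.  Every operation is deterministic, so forward passes and training
runs are bit-for-bit reproducible for fixed weights and seeds.

Implementation notes
--------------------
* Convolution uses cached im2col gather indices and a single matmul; its
  backward scatters with ``np.add.at`` (exact adjoint of the gather).
* Bilinear resampling is expressed as two small interpolation matrices (one
  per spatial axis, ``align_corners=False`` convention); the backward pass is
  the transpose of the same matrices.
* Batch normalization is a fused op with the standard closed-form backward;
  running statistics live in the layer objects, outside the graph.
* Gradients are accumulated through a topologically sorted tape, as in any
  define-by-run framework.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add", "mul", "concat", "relu", "sigmoid", "reshape",
    "conv2d", "maxpool2d", "upsample_bilinear", "batchnorm2d",
    "mean_spatial", "max_spatial", "mean_channel", "max_channel",
    "linear", "bce_with_logits", "add_scalars", "scale",
]

Array = np.ndarray


class Tensor:
    """An array node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data: Array, requires_grad: bool = False) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: Array) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse accumulation from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()


def _make(data: Array, parents: Sequence[Tensor], backward: Callable[[], None] | None) -> Tensor:
    out = Tensor(data)
    needs = any(p.requires_grad or p._parents for p in parents)
    out.requires_grad = needs
    if needs:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (adjoint of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------- basic ops

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward() -> None:
        a._accumulate(_unbroadcast(out.grad, a.data.shape))
        b._accumulate(_unbroadcast(out.grad, b.data.shape))

    out = _make(out_data, (a, b), backward)
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward() -> None:
        a._accumulate(_unbroadcast(out.grad * b.data, a.data.shape))
        b._accumulate(_unbroadcast(out.grad * a.data, b.data.shape))

    out = _make(out_data, (a, b), backward)
    return out


def scale(a: Tensor, c: float) -> Tensor:
    out_data = a.data * c

    def backward() -> None:
        a._accumulate(out.grad * c)

    out = _make(out_data, (a,), backward)
    return out


def add_scalars(terms: Iterable[Tensor]) -> Tensor:
    """Sum of scalar tensors (used to combine weighted loss terms)."""
    terms = list(terms)
    out_data = np.array(sum(float(t.data) for t in terms))

    def backward() -> None:
        for t in terms:
            t._accumulate(np.broadcast_to(out.grad, t.data.shape))

    out = _make(out_data, terms, backward)
    return out


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    out_data = x.data.reshape(shape)

    def backward() -> None:
        x._accumulate(out.grad.reshape(x.data.shape))

    out = _make(out_data, (x,), backward)
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward() -> None:
        x._accumulate(out.grad * mask)

    out = _make(out_data, (x,), backward)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def backward() -> None:
        x._accumulate(out.grad * s * (1.0 - s))

    out = _make(s, (x,), backward)
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward() -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * out_data.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(out.grad[tuple(idx)])

    out = _make(out_data, tuple(tensors), backward)
    return out


# ------------------------------------------------------------- convolution

@lru_cache(maxsize=None)
def _im2col_indices(
    channels: int, kh: int, kw: int, h_out: int, w_out: int, stride: int, dilation: int
) -> tuple[Array, Array, Array]:
    i0 = np.repeat(np.arange(kh) * dilation, kw)
    i0 = np.tile(i0, channels)
    i1 = stride * np.repeat(np.arange(h_out), w_out)
    j0 = np.tile(np.arange(kw) * dilation, kh * channels)
    j1 = stride * np.tile(np.arange(w_out), h_out)
    i = i0.reshape(-1, 1) + i1.reshape(1, -1)
    j = j0.reshape(-1, 1) + j1.reshape(1, -1)
    k = np.repeat(np.arange(channels), kh * kw).reshape(-1, 1)
    return k, i, j


def _conv_out_size(n: int, k: int, stride: int, pad: int, dilation: int) -> int:
    eff = dilation * (k - 1) + 1
    return (n + 2 * pad - eff) // stride + 1


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2-D cross-correlation over NCHW input with OIHW weights."""
    n, c, h, w = x.data.shape
    o, ci, kh, kw = weight.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {ci}")
    h_out = _conv_out_size(h, kh, stride, padding, dilation)
    w_out = _conv_out_size(w, kw, stride, padding, dilation)
    if h_out < 1 or w_out < 1:
        raise ValueError("conv2d output would be empty; input too small")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    k, i, j = _im2col_indices(c, kh, kw, h_out, w_out, stride, dilation)
    cols = xp[:, k, i, j]                       # (n, c*kh*kw, L)
    w2 = weight.data.reshape(o, -1)             # (o, c*kh*kw)
    out_data = np.matmul(w2, cols)              # (n, o, L)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, o, 1)
    out_data = out_data.reshape(n, o, h_out, w_out)

    def backward() -> None:
        g = out.grad.reshape(n, o, -1)          # (n, o, L)
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2)))
        gt = np.ascontiguousarray(g.transpose(1, 0, 2)).reshape(o, -1)
        ct = np.ascontiguousarray(cols.transpose(1, 0, 2)).reshape(cols.shape[1], -1)
        weight._accumulate((gt @ ct.T).reshape(weight.data.shape))
        dcols = np.matmul(w2.T, g)
        dxp = np.zeros_like(xp)
        np.add.at(dxp, (slice(None), k, i, j), dcols)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _make(out_data, parents, backward)
    return out


def maxpool2d(x: Tensor, kernel: int = 2, stride: int | None = None, padding: int = 0) -> Tensor:
    """Max pooling over NCHW input; padded cells are -inf and never win."""
    if stride is None:
        stride = kernel
    n, c, h, w = x.data.shape
    h_out = _conv_out_size(h, kernel, stride, padding, 1)
    w_out = _conv_out_size(w, kernel, stride, padding, 1)
    if h_out < 1 or w_out < 1:
        raise ValueError("maxpool2d output would be empty")
    xp = np.pad(
        x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=-np.inf,
    )
    xr = xp.reshape(n * c, 1, xp.shape[2], xp.shape[3])
    k, i, j = _im2col_indices(1, kernel, kernel, h_out, w_out, stride, 1)
    cols = xr[:, k, i, j]                       # (n*c, kernel*kernel, L)
    arg = np.argmax(cols, axis=1)               # (n*c, L)
    out_data = np.take_along_axis(cols, arg[:, None, :], axis=1)[:, 0, :]
    out_data = out_data.reshape(n, c, h_out, w_out)

    def backward() -> None:
        g = out.grad.reshape(n * c, -1)         # (n*c, L)
        dxp = np.zeros_like(xr)
        rows = i[arg, np.arange(arg.shape[1])[None, :]]
        cols_idx = j[arg, np.arange(arg.shape[1])[None, :]]
        batch_idx = np.repeat(np.arange(n * c), arg.shape[1]).reshape(arg.shape)
        np.add.at(dxp, (batch_idx, 0, rows, cols_idx), g)
        dxp = dxp.reshape(xp.shape)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)

    out = _make(out_data, (x,), backward)
    return out


# --------------------------------------------------------------- resampling

@lru_cache(maxsize=None)
def _bilinear_matrix(n_in: int, n_out: int) -> Array:
    """Row-stochastic interpolation matrix, align_corners=False convention."""
    a = np.zeros((n_out, n_in))
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = src - lo
    a[np.arange(n_out), lo] += 1.0 - t
    a[np.arange(n_out), hi] += t
    return a


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of an NCHW tensor to ``size`` (h, w)."""
    n, c, h, w = x.data.shape
    h2, w2 = size
    ah = _bilinear_matrix(h, h2)
    aw = _bilinear_matrix(w, w2)
    out_data = np.einsum("ij,ncjk,lk->ncil", ah, x.data, aw, optimize=True)

    def backward() -> None:
        g = np.einsum("ij,ncil,lk->ncjk", ah, out.grad, aw, optimize=True)
        x._accumulate(g)

    out = _make(out_data, (x,), backward)
    return out


# ------------------------------------------------------------ normalization

def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: Array,
    running_var: Array,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization with affine parameters.

    In training mode batch statistics are used and ``running_mean`` /
    ``running_var`` are updated in place; in eval mode the running statistics
    are used and left untouched.
    """
    n, c, h, w = x.data.shape
    gam = gamma.data.reshape(1, c, 1, 1)
    bet = beta.data.reshape(1, c, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        m = n * h * w
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * (var * m / max(m - 1, 1))  # unbiased for the running copy
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
        out_data = gam * xhat + bet

        def backward() -> None:
            g = out.grad
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            beta._accumulate(g.sum(axis=(0, 2, 3)))
            dxhat = g * gam
            s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = (inv.reshape(1, c, 1, 1) / m) * (m * dxhat - s1 - xhat * s2)
            x._accumulate(dx)

    else:
        inv = 1.0 / np.sqrt(running_var + eps)
        out_data = gam * ((x.data - running_mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)) + bet
        xhat_eval = (x.data - running_mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)

        def backward() -> None:
            g = out.grad
            gamma._accumulate((g * xhat_eval).sum(axis=(0, 2, 3)))
            beta._accumulate(g.sum(axis=(0, 2, 3)))
            x._accumulate(g * gam * inv.reshape(1, c, 1, 1))

    out = _make(out_data, (x, gamma, beta), backward)
    return out


# -------------------------------------------------------------- reductions

def mean_spatial(x: Tensor) -> Tensor:
    """Global average pool: (N, C, H, W) -> (N, C)."""
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward() -> None:
        g = out.grad[:, :, None, None] / (h * w)
        x._accumulate(np.broadcast_to(g, x.data.shape))

    out = _make(out_data, (x,), backward)
    return out


def max_spatial(x: Tensor) -> Tensor:
    """Global max pool: (N, C, H, W) -> (N, C); gradient flows to the argmax."""
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, -1)
    arg = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def backward() -> None:
        dflat = np.zeros_like(flat)
        ni, ci = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        dflat[ni, ci, arg] = out.grad
        x._accumulate(dflat.reshape(x.data.shape))

    out = _make(out_data, (x,), backward)
    return out


def mean_channel(x: Tensor) -> Tensor:
    """Channel-wise mean: (N, C, H, W) -> (N, 1, H, W)."""
    c = x.data.shape[1]
    out_data = x.data.mean(axis=1, keepdims=True)

    def backward() -> None:
        x._accumulate(np.broadcast_to(out.grad / c, x.data.shape))

    out = _make(out_data, (x,), backward)
    return out


def max_channel(x: Tensor) -> Tensor:
    """Channel-wise max: (N, C, H, W) -> (N, 1, H, W)."""
    arg = x.data.argmax(axis=1)                  # (N, H, W)
    out_data = np.take_along_axis(x.data, arg[:, None, :, :], axis=1)

    def backward() -> None:
        dx = np.zeros_like(x.data)
        np.put_along_axis(dx, arg[:, None, :, :], out.grad, axis=1)
        x._accumulate(dx)

    out = _make(out_data, (x,), backward)
    return out


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Dense layer: (N, C) @ (C, O) + (O,)."""
    out_data = x.data @ weight.data
    if bias is not None:
        out_data = out_data + bias.data

    def backward() -> None:
        g = out.grad
        if bias is not None:
            bias._accumulate(g.sum(axis=0))
        weight._accumulate(x.data.T @ g)
        x._accumulate(g @ weight.data.T)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _make(out_data, parents, backward)
    return out


# ------------------------------------------------------------------- losses

def bce_with_logits(logits: Tensor, target: Array, weight: float = 1.0) -> Tensor:
    """Numerically stable binary cross-entropy on logits, averaged per pixel.

    Equals ``weight * mean(softplus(z) - z*y)``; per-pixel averaging keeps
    gradient magnitudes independent of image size (the pixel-summed value is
    ``this * n_pixels / weight``).
    """
    z = logits.data
    y = np.asarray(target, dtype=np.float64)
    if z.shape != y.shape:
        raise ValueError(f"logits shape {z.shape} vs target shape {y.shape}")
    per_pixel = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out_data = np.array(weight * per_pixel.mean())

    def backward() -> None:
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        logits._accumulate(out.grad * weight * (s - y) / y.size)

    out = _make(out_data, (logits,), backward)
    return out
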