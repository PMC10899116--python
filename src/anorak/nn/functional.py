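"""Differentiable operations for the numpy autograd core.

Every function takes/returns :class:`~anorak.nn.tensor.Tensor` and registers
a backward closure.  Convolution uses an im2col/matmul formulation; bilinear
resampling is expressed as two separable interpolation matrices so that its
adjoint is exact.
"""

from __future__ import annotations

import numpy as np

from . import tensor
from .tensor import Tensor, as_tensor

__all__ = [
    "add", "mul", "power", "matmul", "sum", "mean", "reshape", "transpose",
    "relu", "sigmoid", "softmax", "conv2d", "adaptive_avg_pool2d",
    "upsample_bilinear", "concat", "cross_entropy", "batch_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _needs(*ts) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b) if _needs(a, b) else ())

    def backward(g):
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward if out._parents else None
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b) if _needs(a, b) else ())

    def backward(g):
        a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward if out._parents else None
    return out


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data ** p, parents=(a,) if _needs(a) else ())

    def backward(g):
        a.accumulate(g * p * a.data ** (p - 1.0))

    out._backward = backward if out._parents else None
    return out


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b) if _needs(a, b) else ())

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a.accumulate(_unbroadcast(ga, a.data.shape))
        b.accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = backward if out._parents else None
    return out


def sum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims),
                 parents=(a,) if _needs(a) else ())

    def backward(g):
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, axes)
        a.accumulate(np.broadcast_to(g, a.data.shape))

    out._backward = backward if out._parents else None
    return out


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(sum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.reshape(shape), parents=(a,) if _needs(a) else ())

    def backward(g):
        a.accumulate(g.reshape(a.data.shape))

    out._backward = backward if out._parents else None
    return out


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.transpose(axes), parents=(a,) if _needs(a) else ())
    inv = np.argsort(axes)

    def backward(g):
        a.accumulate(g.transpose(inv))

    out._backward = backward if out._parents else None
    return out


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    out = Tensor(a.data * mask, parents=(a,) if _needs(a) else ())

    def backward(g):
        a.accumulate(g * mask)

    out._backward = backward if out._parents else None
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, parents=(a,) if _needs(a) else ())

    def backward(g):
        a.accumulate(g * s * (1.0 - s))

    out._backward = backward if out._parents else None
    return out


def softmax(a, axis=-1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(a,) if _needs(a) else ())

    def backward(g):
        a.accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    out._backward = backward if out._parents else None
    return out


def concat(tensors, axis=1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors) if _needs(*tensors) else ())
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t.accumulate(g[tuple(idx)])

    out._backward = backward if out._parents else None
    return out


# ---------------------------------------------------------------------------
# spatial operators
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel/stride/padding."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.data.shape
    co, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {ci}")
    s, p = int(stride), int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    ho = (h + 2 * p - kh) // s + 1
    wo = (wd + 2 * p - kw) // s + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    view = view[:, :, ::s, ::s]                     # (n, c, ho, wo, kh, kw)
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(co, c * kh * kw)
    y = cols @ wmat.T
    if b is not None:
        b = as_tensor(b)
        y = y + b.data
    y = y.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
    parents = (x, w) + ((b,) if b is not None else ())
    out = Tensor(y, parents=parents if _needs(*parents) else ())

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
        w.accumulate((gmat.T @ cols).reshape(w.data.shape))
        if b is not None:
            b.accumulate(gmat.sum(axis=0))
        dcols = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
        hp, wp = h + 2 * p, wd + 2 * p
        dxp = np.zeros((n, c, hp, wp), dtype=tensor.DTYPE)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, i, j]
        x.accumulate(dxp[:, :, p:hp - p, p:wp - p] if p else dxp)

    out._backward = backward if out._parents else None
    return out


def _pool_bins(n_in: int, n_out: int):
    starts = (np.arange(n_out) * n_in) // n_out
    ends = -(-(np.arange(1, n_out + 1) * n_in) // n_out)  # ceil division
    return starts, ends


def adaptive_avg_pool2d(x, output_size) -> Tensor:
    """Adaptive average pooling (same bin rule as the usual DL frameworks)."""
    x = as_tensor(x)
    oh, ow = (output_size, output_size) if np.isscalar(output_size) else output_size
    n, c, h, w = x.data.shape
    if oh > h or ow > w:
        raise ValueError(f"pool output {oh}x{ow} larger than input {h}x{w}")
    hs, he = _pool_bins(h, oh)
    ws, we = _pool_bins(w, ow)
    y = np.empty((n, c, oh, ow), dtype=tensor.DTYPE)
    for i in range(oh):
        for j in range(ow):
            y[:, :, i, j] = x.data[:, :, hs[i]:he[i], ws[j]:we[j]].mean(axis=(2, 3))
    out = Tensor(y, parents=(x,) if _needs(x) else ())

    def backward(g):
        dx = np.zeros_like(x.data)
        for i in range(oh):
            for j in range(ow):
                area = (he[i] - hs[i]) * (we[j] - ws[j])
                dx[:, :, hs[i]:he[i], ws[j]:we[j]] += g[:, :, i, j, None, None] / area
        x.accumulate(dx)

    out._backward = backward if out._parents else None
    return out


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centers)."""
    m = np.zeros((n_out, n_in), dtype=tensor.DTYPE)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def upsample_bilinear(x, size) -> Tensor:
    x = as_tensor(x)
    oh, ow = (size, size) if np.isscalar(size) else size
    _, _, h, w = x.data.shape
    a = _interp_matrix(oh, h)
    bm = _interp_matrix(ow, w)
    y = np.einsum("ij,ncjk,lk->ncil", a, x.data, bm, optimize=True)
    out = Tensor(y, parents=(x,) if _needs(x) else ())

    def backward(g):
        x.accumulate(np.einsum("ij,ncil,lk->ncjk", a, g, bm, optimize=True))

    out._backward = backward if out._parents else None
    return out


# ---------------------------------------------------------------------------
# losses / normalization
# ---------------------------------------------------------------------------

def cross_entropy(logits, labels) -> Tensor:
    """Mean pixel-wise cross entropy; logits (N,K,H,W), labels (N,H,W) int."""
    logits = as_tensor(logits)
    lab = np.asarray(labels)
    n, k, h, w = logits.data.shape
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    ii, hh, ww = np.ogrid[:n, :h, :w]
    loss = -np.mean(np.log(p[ii, lab, hh, ww] + 1e-12))
    out = Tensor(loss, parents=(logits,) if _needs(logits) else ())

    def backward(g):
        d = p.copy()
        d[ii, lab, hh, ww] -= 1.0
        logits.accumulate(g * d / (n * h * w))

    out._backward = backward if out._parents else None
    return out


def batch_norm(x, gamma, beta, running_mean, running_var,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N,H,W); updates running stats."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    g4 = gamma.data.reshape(1, -1, 1, 1)
    b4 = beta.data.reshape(1, -1, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
        var = x.data.var(axis=(0, 2, 3), keepdims=True)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu.ravel()
        running_var *= 1.0 - momentum
        running_var += momentum * var.ravel()
    else:
        mu = running_mean.reshape(1, -1, 1, 1)
        var = running_var.reshape(1, -1, 1, 1)
    ivstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * ivstd
    out = Tensor(xhat * g4 + b4,
                 parents=(x, gamma, beta) if _needs(x, gamma, beta) else ())
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta.accumulate(g.sum(axis=(0, 2, 3)))
        dxhat = g * g4
        if training:
            dx = (ivstd / m) * (m * dxhat
                                - dxhat.sum(axis=(0, 2, 3), keepdims=True)
                                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True))
        else:
            dx = dxhat * ivstd
        x.accumulate(dx)

    out._backward = backward if out._parents else None
    return out
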