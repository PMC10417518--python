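"""Differentiable array operations (NHWC layout).

Convolutions are computed as a sum of shifted GEMMs: for each kernel tap
(ki, kj) the correspondingly shifted input window is flattened and
multiplied with that tap's (C_in, C_out) weight slice. This maps all of
the arithmetic onto BLAS matrix products, which is the fastest route
available to a pure-numpy engine, and makes strides and dilations a matter
of slice indexing.

Weight layouts: dense conv ``(kh, kw, C_in, C_out)``, depthwise conv
``(kh, kw, C)``, linear ``(in, out)``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .tensor import Tensor

__all__ = [
    "add", "mul", "concat", "reshape", "sum_all",
    "relu", "relu6", "hswish", "hsigmoid",
    "conv2d", "depthwise_conv2d", "linear",
    "batch_norm", "global_avg_pool", "upsample_bilinear",
    "softmax_cross_entropy",
]


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    ndim_diff = g.ndim - len(shape)
    if ndim_diff > 0:
        g = g.sum(axis=tuple(range(ndim_diff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data
    needs = a.requires_grad or b.requires_grad or a._parents or b._parents

    def backward(g):
        a.accumulate_grad(_unbroadcast(g, a.data.shape))
        b.accumulate_grad(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward_fn=backward if needs is not None else None)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        a.accumulate_grad(_unbroadcast(g * b.data, a.data.shape))
        b.accumulate_grad(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward_fn=backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t.accumulate_grad(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward_fn=backward)


def reshape(x: Tensor, shape: tuple) -> Tensor:
    out_data = x.data.reshape(shape)

    def backward(g):
        x.accumulate_grad(g.reshape(x.data.shape))

    return Tensor(out_data, parents=(x,), backward_fn=backward)


def sum_all(x: Tensor) -> Tensor:
    out_data = np.asarray(x.data.sum())

    def backward(g):
        x.accumulate_grad(np.broadcast_to(g, x.data.shape).astype(x.data.dtype))

    return Tensor(out_data, parents=(x,), backward_fn=backward)


# -- activations -------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0)

    def backward(g):
        x.accumulate_grad(g * (x.data > 0))

    return Tensor(out_data, parents=(x,), backward_fn=backward)


def relu6(x: Tensor) -> Tensor:
    out_data = np.clip(x.data, 0, 6)

    def backward(g):
        x.accumulate_grad(g * ((x.data > 0) & (x.data < 6)))

    return Tensor(out_data, parents=(x,), backward_fn=backward)


def hswish(x: Tensor) -> Tensor:
    """Hard swish: x * clip(x + 3, 0, 6) / 6 (piecewise-linear swish)."""
    inner = np.clip(x.data + 3.0, 0.0, 6.0)
    out_data = x.data * inner / 6.0

    def backward(g):
        d = np.where(x.data <= -3.0, 0.0, np.where(x.data >= 3.0, 1.0, (2.0 * x.data + 3.0) / 6.0))
        x.accumulate_grad(g * d.astype(x.data.dtype))

    return Tensor(out_data, parents=(x,), backward_fn=backward)


def hsigmoid(x: Tensor) -> Tensor:
    """Hard sigmoid: clip(x + 3, 0, 6) / 6, range [0, 1]."""
    out_data = np.clip(x.data + 3.0, 0.0, 6.0) / 6.0

    def backward(g):
        d = ((x.data > -3.0) & (x.data < 3.0)).astype(x.data.dtype) / 6.0
        x.accumulate_grad(g * d)

    return Tensor(out_data, parents=(x,), backward_fn=backward)


# -- convolutions ------------------------------------------------------------

def _out_size(size: int, k: int, stride: int, dilation: int, pad: int) -> int:
    eff = dilation * (k - 1) + 1
    return (size + 2 * pad - eff) // stride + 1


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Optional[Tensor] = None,
    stride: int = 1,
    dilation: int = 1,
    padding: Optional[int] = None,
) -> Tensor:
    """2-D convolution, NHWC input, ``(kh, kw, C_in, C_out)`` weight.

    Default padding keeps the spatial size at stride 1 (``d*(k-1)//2``).
    """
    kh, kw, cin, cout = w.data.shape
    if padding is None:
        padding = dilation * (kh - 1) // 2
    n, h, ww_, c = x.data.shape
    if c != cin:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {cin}")
    ho = _out_size(h, kh, stride, dilation, padding)
    wo = _out_size(ww_, kw, stride, dilation, padding)
    xp = np.pad(x.data, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    acc = np.zeros((n * ho * wo, cout), dtype=x.data.dtype)
    for ki in range(kh):
        for kj in range(kw):
            hi = ki * dilation
            wi = kj * dilation
            xs = xp[:, hi : hi + stride * (ho - 1) + 1 : stride,
                    wi : wi + stride * (wo - 1) + 1 : stride, :]
            acc += xs.reshape(-1, cin) @ w.data[ki, kj]
    out_data = acc.reshape(n, ho, wo, cout)
    if b is not None:
        out_data = out_data + b.data

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gf = g.reshape(-1, cout)
        gw = np.zeros_like(w.data)
        gxp = np.zeros_like(xp)
        for ki in range(kh):
            for kj in range(kw):
                hi = ki * dilation
                wi = kj * dilation
                sl = (slice(None),
                      slice(hi, hi + stride * (ho - 1) + 1, stride),
                      slice(wi, wi + stride * (wo - 1) + 1, stride),
                      slice(None))
                xs = xp[sl]
                gw[ki, kj] = xs.reshape(-1, cin).T @ gf
                gxp[sl] += (gf @ w.data[ki, kj].T).reshape(n, ho, wo, cin)
        w.accumulate_grad(gw)
        if padding:
            x.accumulate_grad(gxp[:, padding:padding + h, padding:padding + ww_, :])
        else:
            x.accumulate_grad(gxp)
        if b is not None:
            b.accumulate_grad(gf.sum(axis=0).reshape(b.data.shape))

    return Tensor(out_data, parents=parents, backward_fn=backward)


def depthwise_conv2d(
    x: Tensor,
    w: Tensor,
    stride: int = 1,
    dilation: int = 1,
    padding: Optional[int] = None,
) -> Tensor:
    """Depthwise 2-D convolution: one ``kh×kw`` filter per channel."""
    kh, kw, c = w.data.shape
    if padding is None:
        padding = dilation * (kh - 1) // 2
    n, h, ww_, cx = x.data.shape
    if cx != c:
        raise ValueError(f"depthwise_conv2d: input has {cx} channels, weight expects {c}")
    ho = _out_size(h, kh, stride, dilation, padding)
    wo = _out_size(ww_, kw, stride, dilation, padding)
    xp = np.pad(x.data, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    out_data = np.zeros((n, ho, wo, c), dtype=x.data.dtype)
    for ki in range(kh):
        for kj in range(kw):
            hi = ki * dilation
            wi = kj * dilation
            xs = xp[:, hi : hi + stride * (ho - 1) + 1 : stride,
                    wi : wi + stride * (wo - 1) + 1 : stride, :]
            out_data += xs * w.data[ki, kj]

    def backward(g):
        gw = np.zeros_like(w.data)
        gxp = np.zeros_like(xp)
        for ki in range(kh):
            for kj in range(kw):
                hi = ki * dilation
                wi = kj * dilation
                sl = (slice(None),
                      slice(hi, hi + stride * (ho - 1) + 1, stride),
                      slice(wi, wi + stride * (wo - 1) + 1, stride),
                      slice(None))
                gw[ki, kj] = (xp[sl] * g).sum(axis=(0, 1, 2))
                gxp[sl] += g * w.data[ki, kj]
        w.accumulate_grad(gw)
        if padding:
            x.accumulate_grad(gxp[:, padding:padding + h, padding:padding + ww_, :])
        else:
            x.accumulate_grad(gxp)

    return Tensor(out_data, parents=(x, w), backward_fn=backward)


def linear(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    out_data = x.data @ w.data
    if b is not None:
        out_data = out_data + b.data
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        x.accumulate_grad(g @ w.data.T)
        w.accumulate_grad(x.data.T @ g)
        if b is not None:
            b.accumulate_grad(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=parents, backward_fn=backward)


# -- normalisation and pooling ----------------------------------------------

def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalisation over (N, H, W) per channel.

    In training mode batch statistics are used and the running estimates
    are updated in place; in eval mode the running estimates are used.
    """
    axes = (0, 1, 2)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        # unbiased variance for the running estimate
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out_data = (gamma.data * xhat + beta.data).astype(x.data.dtype)

    def backward(g):
        gamma.accumulate_grad((g * xhat).sum(axis=axes))
        beta.accumulate_grad(g.sum(axis=axes))
        if training:
            gm = g.mean(axis=axes)
            gxm = (g * xhat).mean(axis=axes)
            gx = gamma.data * inv_std * (g - gm - xhat * gxm)
        else:
            gx = gamma.data * inv_std * g
        x.accumulate_grad(gx.astype(x.data.dtype))

    return Tensor(out_data, parents=(x, gamma, beta), backward_fn=backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial axes, keeping them as size 1 (N,1,1,C)."""
    n, h, w, c = x.data.shape
    out_data = x.data.mean(axis=(1, 2), keepdims=True)

    def backward(g):
        x.accumulate_grad(np.broadcast_to(g / (h * w), x.data.shape).astype(x.data.dtype))

    return Tensor(out_data, parents=(x,), backward_fn=backward)


_interp_cache: dict = {}


def _interp_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """1-D bilinear interpolation matrix (half-pixel centres)."""
    key = (n_in, n_out, np.dtype(dtype).str)
    m = _interp_cache.get(key)
    if m is None:
        m = np.zeros((n_out, n_in), dtype=dtype)
        scale = n_in / n_out
        for o in range(n_out):
            src = (o + 0.5) * scale - 0.5
            i0 = int(np.floor(src))
            frac = src - i0
            i0c = min(max(i0, 0), n_in - 1)
            i1c = min(max(i0 + 1, 0), n_in - 1)
            m[o, i0c] += 1.0 - frac
            m[o, i1c] += frac
        _interp_cache[key] = m
    return m


def upsample_bilinear(x: Tensor, scale: int) -> Tensor:
    """Bilinear up-sampling by an integer factor (half-pixel convention).

    Implemented as two 1-D interpolation matrix products, so the backward
    pass is the exact transpose.
    """
    n, h, w, c = x.data.shape
    mh = _interp_matrix(h, h * scale, x.data.dtype)
    mw = _interp_matrix(w, w * scale, x.data.dtype)
    # (N,H,W,C) -> interpolate H then W via tensordot, keeping NHWC order
    t = np.tensordot(mh, x.data, axes=([1], [1]))        # (Ho, N, W, C)
    out_data = np.tensordot(mw, t, axes=([1], [2]))      # (Wo, Ho, N, C)
    out_data = out_data.transpose(2, 1, 0, 3).copy()     # (N, Ho, Wo, C)

    def backward(g):
        gt = np.tensordot(mw.T, g.transpose(2, 1, 0, 3), axes=([1], [0]))  # (W, Ho, N, C)
        gx = np.tensordot(mh.T, gt, axes=([1], [1]))                       # (H, W, N, C)
        x.accumulate_grad(gx.transpose(2, 0, 1, 3))

    return Tensor(out_data, parents=(x,), backward_fn=backward)


# -- loss --------------------------------------------------------------------

def softmax_cross_entropy(
    logits: Tensor,
    labels: np.ndarray,
    ignore_index: Optional[int] = None,
) -> Tensor:
    """Mean per-pixel cross-entropy between NHWC logits and integer labels."""
    nc = logits.data.shape[-1]
    flat = logits.data.reshape(-1, nc)
    lab = np.asarray(labels).reshape(-1)
    if ignore_index is not None:
        valid = lab != ignore_index
    else:
        valid = np.ones(lab.shape, dtype=bool)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("cross-entropy: no valid pixels to score")
    z = flat - flat.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    lab_safe = np.where(valid, lab, 0)
    nll = -logp[np.arange(lab.shape[0]), lab_safe]
    nll[~valid] = 0.0
    loss = np.asarray(nll.sum() / n_valid, dtype=logits.data.dtype)

    def backward(g):
        p = np.exp(logp)
        p[np.arange(lab.shape[0]), lab_safe] -= 1.0
        p[~valid] = 0.0
        grad = (g * p / n_valid).reshape(logits.data.shape).astype(logits.data.dtype)
        logits.accumulate_grad(grad)

    return Tensor(loss, parents=(logits,), backward_fn=backward)
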