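"""Differentiable 3D tensor ops on numpy arrays.

Layout convention is (N, C, D, H, W) throughout.  The convolution
primitives carry hand-written vector-Jacobian products registered with
``autograd`` — a traced 27-term shifted-slice convolution is an order of
magnitude slower to differentiate than the closed-form backward pass, and
these five primitives dominate the cost of a training step.  Everything
else (normalisation, activations, pooling) is written in ``autograd.numpy``
and differentiated automatically.
"""

from __future__ import annotations

import numpy as np
import autograd.numpy as anp
from autograd.extend import defvjp, primitive
from autograd.scipy.special import erf
from scipy.special import expit

__all__ = [
    "dwconv3d",
    "pwconv3d",
    "conv3d",
    "interleave_zeros",
    "dwconv_transpose3d_s2",
    "pwconv_transpose3d_s2",
    "channel_norm",
    "batch_norm",
    "gelu",
    "sigmoid",
    "softmax_channels",
    "global_avg_pool",
    "global_max_pool",
]


def _out_len(n: int, k: int, stride: int) -> int:
    p = k // 2
    return (n + 2 * p - k) // stride + 1


# ---------------------------------------------------------------------------
# depthwise k x k x k convolution (optionally strided), zero padding k//2
# ---------------------------------------------------------------------------

def _dw_slices(shape, k, stride):
    """Yield (i, j, l, slice-tuple) covering every kernel offset."""
    _, _, D, H, W = shape
    do, ho, wo = (_out_len(n, k, stride) for n in (D, H, W))
    for i in range(k):
        for j in range(k):
            for l in range(k):
                yield i, j, l, (
                    slice(None),
                    slice(None),
                    slice(i, i + (do - 1) * stride + 1, stride),
                    slice(j, j + (ho - 1) * stride + 1, stride),
                    slice(l, l + (wo - 1) * stride + 1, stride),
                )


def _pad_spatial(x, p):
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))


@primitive
def dwconv3d(x, w, b, stride=1):
    """Depthwise (grouped per-channel) conv; ``w`` is (C, k, k, k)."""
    k = w.shape[-1]
    xp = _pad_spatial(x, k // 2)
    out = None
    for i, j, l, sl in _dw_slices(x.shape, k, stride):
        term = w[:, i, j, l][None, :, None, None, None] * xp[sl]
        out = term if out is None else out + term
    if b is not None:
        out = out + b[None, :, None, None, None]
    return out


def _dwconv3d_vjp_x(ans, x, w, b, stride=1):
    def vjp(g):
        k = w.shape[-1]
        p = k // 2
        N, C, D, H, W = x.shape
        gxp = np.zeros((N, C, D + 2 * p, H + 2 * p, W + 2 * p), dtype=g.dtype)
        for i, j, l, sl in _dw_slices(x.shape, k, stride):
            gxp[sl] += w[:, i, j, l][None, :, None, None, None] * g
        return gxp[:, :, p : p + D, p : p + H, p : p + W]

    return vjp


def _dwconv3d_vjp_w(ans, x, w, b, stride=1):
    def vjp(g):
        k = w.shape[-1]
        xp = _pad_spatial(x, k // 2)
        gw = np.empty_like(w)
        for i, j, l, sl in _dw_slices(x.shape, k, stride):
            gw[:, i, j, l] = np.einsum("ncdhw,ncdhw->c", g, xp[sl])
        return gw

    return vjp


defvjp(
    dwconv3d,
    _dwconv3d_vjp_x,
    _dwconv3d_vjp_w,
    lambda ans, x, w, b, stride=1: lambda g: g.sum(axis=(0, 2, 3, 4)),
)


# ---------------------------------------------------------------------------
# pointwise 1 x 1 x 1 convolution
# ---------------------------------------------------------------------------

@primitive
def pwconv3d(x, w, b):
    """1x1x1 conv; ``w`` is (C_out, C_in)."""
    N, C, D, H, W = x.shape
    out = np.matmul(w, x.reshape(N, C, -1)).reshape(N, w.shape[0], D, H, W)
    if b is not None:
        out = out + b[None, :, None, None, None]
    return out


defvjp(
    pwconv3d,
    lambda ans, x, w, b: lambda g: np.matmul(
        w.T, g.reshape(g.shape[0], g.shape[1], -1)
    ).reshape(x.shape),
    lambda ans, x, w, b: lambda g: np.einsum(
        "nov,ncv->oc",
        g.reshape(g.shape[0], g.shape[1], -1),
        x.reshape(x.shape[0], x.shape[1], -1),
    ),
    lambda ans, x, w, b: lambda g: g.sum(axis=(0, 2, 3, 4)),
)


# ---------------------------------------------------------------------------
# dense (non-grouped) k x k x k convolution, zero padding k//2
# ---------------------------------------------------------------------------

@primitive
def conv3d(x, w, b, stride=1):
    """Full conv; ``w`` is (C_out, C_in, k, k, k).  Used for small kernels
    over few channels (e.g. the CBAM spatial gate)."""
    k = w.shape[-1]
    N, C, D, H, W = x.shape
    xp = _pad_spatial(x, k // 2)
    do, ho, wo = (_out_len(n, k, stride) for n in (D, H, W))
    out = np.zeros((N, w.shape[0], do, ho, wo), dtype=x.dtype)
    for i, j, l, sl in _dw_slices(x.shape, k, stride):
        xs = xp[sl]
        out += np.matmul(w[:, :, i, j, l], xs.reshape(N, C, -1)).reshape(out.shape)
    if b is not None:
        out = out + b[None, :, None, None, None]
    return out


def _conv3d_vjp_x(ans, x, w, b, stride=1):
    def vjp(g):
        k = w.shape[-1]
        p = k // 2
        N, C, D, H, W = x.shape
        gr = g.reshape(g.shape[0], g.shape[1], -1)
        gxp = np.zeros((N, C, D + 2 * p, H + 2 * p, W + 2 * p), dtype=g.dtype)
        for i, j, l, sl in _dw_slices(x.shape, k, stride):
            gxp[sl] += np.matmul(w[:, :, i, j, l].T, gr).reshape(
                N, C, g.shape[2], g.shape[3], g.shape[4]
            )
        return gxp[:, :, p : p + D, p : p + H, p : p + W]

    return vjp


def _conv3d_vjp_w(ans, x, w, b, stride=1):
    def vjp(g):
        k = w.shape[-1]
        xp = _pad_spatial(x, k // 2)
        gr = g.reshape(g.shape[0], g.shape[1], -1)
        gw = np.empty_like(w)
        for i, j, l, sl in _dw_slices(x.shape, k, stride):
            xs = xp[sl].reshape(x.shape[0], x.shape[1], -1)
            gw[:, :, i, j, l] = np.einsum("nov,ncv->oc", gr, xs)
        return gw

    return vjp


defvjp(
    conv3d,
    _conv3d_vjp_x,
    _conv3d_vjp_w,
    lambda ans, x, w, b, stride=1: lambda g: g.sum(axis=(0, 2, 3, 4)),
)


# ---------------------------------------------------------------------------
# 2x transposed convolutions (stride 2), built from zero-stuffing + conv
# ---------------------------------------------------------------------------

def interleave_zeros(x, axis):
    """Insert a zero between consecutive entries along ``axis``
    (length n -> 2n - 1).  Differentiable through autograd."""
    xm = anp.swapaxes(x, axis, -1)
    stacked = anp.stack([xm, anp.zeros_like(xm)], axis=-1)
    flat = anp.reshape(stacked, xm.shape[:-1] + (2 * xm.shape[-1],))
    return anp.swapaxes(flat[..., :-1], axis, -1)


def _zero_stuff(x):
    for ax in (2, 3, 4):
        x = interleave_zeros(x, ax)
    return x


def _flip_kernel(w):
    return w[..., ::-1, ::-1, ::-1]


def dwconv_transpose3d_s2(x, w, b):
    """Depthwise transposed conv, kernel k, stride 2, padding k//2,
    followed by a leading zero-pad so every spatial axis exactly doubles
    (n -> 2n).  ``w`` is (C, k, k, k)."""
    y = dwconv3d(_zero_stuff(x), _flip_kernel(w), b, 1)
    return anp.pad(y, ((0, 0), (0, 0), (1, 0), (1, 0), (1, 0)), mode="constant")


def pwconv_transpose3d_s2(x, w, b):
    """1x1x1 transposed conv with stride 2 (+ leading zero-pad to 2n).
    Used on the residual path of the decoder's up blocks."""
    y = pwconv3d(_zero_stuff(x), w, b)
    return anp.pad(y, ((0, 0), (0, 0), (1, 0), (1, 0), (1, 0)), mode="constant")


# ---------------------------------------------------------------------------
# normalisation / activations / pooling
# ---------------------------------------------------------------------------

_EPS = 1e-5


def channel_norm(x, gamma, beta):
    """Group normalisation with one group per channel (statistics over the
    spatial grid of each sample/channel)."""
    m = anp.mean(x, axis=(2, 3, 4), keepdims=True)
    v = anp.mean((x - m) ** 2, axis=(2, 3, 4), keepdims=True)
    y = (x - m) / anp.sqrt(v + _EPS)
    return y * gamma[None, :, None, None, None] + beta[None, :, None, None, None]


def batch_norm(x, gamma, beta):
    """Batch normalisation using the statistics of the current batch in both
    training and inference (the model stays a pure function of its inputs)."""
    m = anp.mean(x, axis=(0, 2, 3, 4), keepdims=True)
    v = anp.mean((x - m) ** 2, axis=(0, 2, 3, 4), keepdims=True)
    y = (x - m) / anp.sqrt(v + _EPS)
    return y * gamma[None, :, None, None, None] + beta[None, :, None, None, None]


def gelu(x):
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0).astype(np.float32)))


@primitive
def sigmoid(x):
    return expit(x)


defvjp(sigmoid, lambda ans, x: lambda g: g * ans * (1.0 - ans))


def softmax_channels(x):
    """Numerically stable softmax over the channel axis."""
    z = x - anp.max(x, axis=1, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=1, keepdims=True)


def global_avg_pool(x):
    return anp.mean(x, axis=(2, 3, 4))


def global_max_pool(x):
    return anp.max(x, axis=(2, 3, 4))
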