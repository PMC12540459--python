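"""3D Gaussian/Laplacian pyramid.

The pyramid decomposes a volume ``N`` into per-level high-frequency
residuals::

    N_0 = N
    N_{k+1} = d(gs(N_k))          # Gaussian smooth, then 2x decimation
    L_k = N_k - up(N_{k+1})       # residual against the upsampled coarse level

so that ``N_k = L_k + up(N_{k+1})`` reconstructs the input exactly.  The
residuals carry edge and texture detail at each scale; the first two levels
feed the edge-attention blocks of the network.

Conventions (the classic Burt–Adelson pyramid):

* ``gs`` is the separable 5-tap binomial kernel [1, 4, 6, 4, 1]/16 — unit
  sum and symmetric, so constants are reproduced exactly and interior affine
  ramps are preserved;
* borders are mirror-reflected, keeping the constant/affine properties at
  the boundary;
* decimation keeps voxels (0, 2, 4, ...), giving ceil(n/2) per axis;
* upsampling is trilinear interpolation to an explicit target shape (either
  2n-1 or 2n of the coarse shape), so round trips restore shapes exactly.

The functional layer (:func:`smooth3`, :func:`decimate2`, :func:`resize_linear3`)
acts on the trailing three axes of any array and is written with
``autograd.numpy``, so the same code is differentiable when used inside the
network's fusion blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import autograd.numpy as anp
import numpy as np

__all__ = [
    "Volume",
    "LaplacianPyramid",
    "gaussian_smooth",
    "downsample2",
    "upsample2",
    "build_laplacian_pyramid",
    "smooth3",
    "decimate2",
    "resize_linear3",
]

_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class Volume:
    """A 3D scalar grid with physical voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {v.shape}")
        if any(n < 1 for n in v.shape):
            raise ValueError(f"every axis must have length >= 1, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite values")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class LaplacianPyramid:
    """Laplacian levels L_0..L_{K-1} plus the top Gaussian level N_K."""

    levels: tuple
    top: Volume
    source_shape: tuple

    def __len__(self):
        return len(self.levels)

    def reconstruct(self) -> Volume:
        """Invert the decomposition: N_k = L_k + up(N_{k+1})."""
        n = self.top
        for lev in reversed(self.levels):
            up = upsample2(n, lev.shape)
            n = Volume(lev.values + up.values, lev.spacing)
        return n


# ---------------------------------------------------------------------------
# functional layer (autograd-differentiable, trailing 3 axes)
# ---------------------------------------------------------------------------

def _reflect_index(n: int, pad: int) -> np.ndarray:
    mode = "reflect" if n > pad else "symmetric"
    return np.pad(np.arange(n), pad, mode=mode)


def _smooth_last(x):
    n = x.shape[-1]
    if n >= 3:
        # reflect-pad by concatenating reversed edge slices: cheap to
        # differentiate (the adjoint of concatenate is a split)
        xp = anp.concatenate([x[..., 2:0:-1], x, x[..., -2:-4:-1]], axis=-1)
    else:
        idx = _reflect_index(n, 2)
        xp = x[..., idx]
    # python-float taps keep the input dtype (no silent float64 upcast)
    out = float(_KERNEL[0]) * xp[..., 0:n]
    for t in range(1, 5):
        out = out + float(_KERNEL[t]) * xp[..., t : t + n]
    return out


def smooth3(x):
    """Separable binomial smoothing over the trailing three axes."""
    for ax in (-3, -2, -1):
        x = anp.swapaxes(_smooth_last(anp.swapaxes(x, ax, -1)), ax, -1)
    return x


def decimate2(x):
    """Keep every second voxel along the trailing three axes."""
    return x[..., ::2, ::2, ::2]


def _resize_axis_last(x, m: int):
    n = x.shape[-1]
    if m == n:
        return x
    if n == 1:
        return x[..., np.zeros(m, dtype=int)]
    src = np.arange(m) * (n - 1) / (m - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n - 1)
    dtype = getattr(x, "dtype", np.float64)
    w = (src - i0).astype(dtype)
    one = dtype.type(1.0) if hasattr(dtype, "type") else 1.0
    return x[..., i0] * (one - w) + x[..., i1] * w


def resize_linear3(x, target_shape: Sequence[int]):
    """Trilinear (separable linear) resize of the trailing three axes."""
    for ax, m in zip((-3, -2, -1), target_shape):
        x = anp.swapaxes(_resize_axis_last(anp.swapaxes(x, ax, -1), int(m)), ax, -1)
    return x


def highpass3(x):
    """One-level Laplacian residual of the trailing three axes:
    ``x - up(d(gs(x)))``.  Differentiable; used by the fusion blocks."""
    coarse = decimate2(smooth3(x))
    return x - resize_linear3(coarse, x.shape[-3:])


# ---------------------------------------------------------------------------
# Volume-level operations
# ---------------------------------------------------------------------------

def _check(vol: Volume) -> Volume:
    if not isinstance(vol, Volume):
        vol = Volume(np.asarray(vol))
    return vol


def gaussian_smooth(vol: Volume) -> Volume:
    """Unit-sum symmetric Gaussian (binomial) smoothing, reflect borders."""
    vol = _check(vol)
    return Volume(smooth3(vol.values), vol.spacing)


def downsample2(vol: Volume) -> Volume:
    """2x decimation: output voxel (i,j,k) = input voxel (2i,2j,2k); spacing
    doubles; per-axis length becomes ceil(n/2)."""
    vol = _check(vol)
    return Volume(decimate2(vol.values), tuple(2 * s for s in vol.spacing))


def upsample2(vol: Volume, target_shape: Sequence[int]) -> Volume:
    """Trilinear upsampling to ``target_shape``; each target axis must be
    2n-1 or 2n of the source axis length n."""
    vol = _check(vol)
    target_shape = tuple(int(m) for m in target_shape)
    for n, m in zip(vol.shape, target_shape):
        if m not in (2 * n - 1, 2 * n):
            raise ValueError(
                f"target axis {m} incompatible with 2x upsampling of {n} "
                f"(expected {2 * n - 1} or {2 * n})"
            )
    values = resize_linear3(vol.values, target_shape)
    spacing = tuple(s * n / m for s, n, m in zip(vol.spacing, vol.shape, target_shape))
    return Volume(values, spacing)


def build_laplacian_pyramid(vol: Volume, K: int) -> LaplacianPyramid:
    """Build the K-level Laplacian pyramid (levels L_0..L_{K-1}, top N_K)."""
    vol = _check(vol)
    if K < 1:
        raise ValueError("K must be >= 1")
    if any(n < 2**K for n in vol.shape):
        raise ValueError(f"volume shape {vol.shape} too small for K={K} levels")
    levels = []
    n_k = vol
    for _ in range(K):
        n_next = downsample2(gaussian_smooth(n_k))
        up = upsample2(n_next, n_k.shape)
        levels.append(Volume(n_k.values - up.values, n_k.spacing))
        n_k = n_next
    return LaplacianPyramid(tuple(levels), n_k, vol.shape)
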