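"""Synthetic multimodal lesion phantoms.

Real cases are multimodal brain volumes containing one small, low-contrast
cortical lesion with poorly defined edges.  The generator emulates exactly
those properties on a controllable grid:

* a head analog: an ellipsoidal support holding two smoothly interleaved
  "tissue" compartments (a thresholded smoothed random field), mimicking the
  grey/white intensity structure that makes subtle lesions hard to see;
* lesions: random ellipsoids placed fully inside the head, with
  Gaussian-blurred boundaries (the hallmark blurred edge) and a
  modality-specific additive contrast — slightly hypointense on the T1
  analog, hyperintense on the FLAIR analog, hypometabolic (hypointense) on
  the PET analog;
* the ground truth is the *pre-blur* ellipsoid support;
* additive Gaussian noise.

Defaults reflect the study conditions: a 128^3 grid at 1 mm spacing, one
lesion per case (the clinical cohorts average one annotated lesion per
patient), lesion semi-axes of 4-12 voxels (well under 2% of the head
volume), blur sigma 1.5 mm, and low contrast relative to the tissue gap.
Every case is a deterministic function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

from .data import MultimodalCase, save_case, write_manifest

__all__ = ["SyntheticParams", "generate_synthetic_case", "write_synthetic_dataset"]

_TISSUE_LOW, _TISSUE_HIGH = 1.0, 1.4


@dataclass(frozen=True)
class SyntheticParams:
    shape: Tuple[int, int, int] = (128, 128, 128)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lesions: int = 1
    semiaxes_range: Tuple[float, float] = (4.0, 12.0)   # voxels
    edge_blur_sigma: float = 1.5                        # voxels (= mm at 1 mm)
    contrasts: Tuple[Tuple[str, float], ...] = (
        ("t1", -0.3),      # slight hypointensity
        ("flair", 0.8),    # hyperintensity
        ("pet", -0.6),     # hypometabolism
    )
    background_smoothness: float = 4.0                  # voxels
    noise_sd: float = 0.1
    seed: int = 0
    max_tries: int = 200

    def __post_init__(self):
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        lo, hi = self.semiaxes_range
        if not (0 < lo <= hi):
            raise ValueError("invalid semi-axes range")
        if any(n < 16 for n in self.shape):
            raise ValueError("grid too small for a head analog")


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = 0.0
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def generate_synthetic_case(params: SyntheticParams, case_id: str = None) -> MultimodalCase:
    """Generate one multimodal case; bit-identical for identical params."""
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.shape)

    head = _ellipsoid(shape, [n / 2 - 0.5 for n in shape], [0.45 * n for n in shape])

    # two-compartment tissue analog from a thresholded smooth random field
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), params.background_smoothness)
    tissue = np.where(tex > np.median(tex[head]), _TISSUE_HIGH, _TISSUE_LOW)
    tissue = tissue * head

    gt = np.zeros(shape, dtype=bool)
    head_volume = int(head.sum())
    for _ in range(params.n_lesions):
        placed = False
        for _try in range(params.max_tries):
            semi = rng.uniform(*params.semiaxes_range, size=3)
            margin = semi + 1
            center = [rng.uniform(m, n - 1 - m) for m, n in zip(margin, shape)]
            les = _ellipsoid(shape, center, semi)
            if not les.any():
                continue
            if np.all(head[les]) and (gt.sum() + les.sum()) < 0.02 * head_volume:
                gt |= les
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place a lesion inside the head analog after {params.max_tries} tries"
            )

    soft = ndimage.gaussian_filter(gt.astype(np.float64), params.edge_blur_sigma)

    volumes: Dict[str, np.ndarray] = {}
    for name, contrast in params.contrasts:
        noise = rng.standard_normal(shape) * params.noise_sd
        vol = (tissue + contrast * soft + noise) * head
        volumes[name] = vol
    case_id = case_id or f"synthetic_{params.seed:06d}"
    return MultimodalCase(case_id, volumes, gt.astype(np.uint8),
                          affine=np.diag(list(params.spacing) + [1.0]),
                          spacing=params.spacing)


def write_synthetic_dataset(out_dir, n_cases: int, params: SyntheticParams = SyntheticParams()):
    """Write ``n_cases`` phantom cases + manifest; case i uses seed+i."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = []
    for i in range(n_cases):
        p = SyntheticParams(**{**params.__dict__, "seed": (params.seed + i) % (2**31)})
        case = generate_synthetic_case(p, case_id=f"case_{i:03d}")
        save_case(case, out_dir)
        ids.append(case.case_id)
    write_manifest(out_dir, ids, [name for name, _ in params.contrasts])
    return ids
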