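"""NIfTI I/O, preprocessing and dataset handling.

A case is a set of co-registered modality volumes (T1 required; FLAIR and
PET optional) plus a binary lesion mask on the same grid.  On disk a dataset
is one directory per case::

    <root>/<case>/<case>_t1.nii.gz
    <root>/<case>/<case>_flair.nii.gz      (optional)
    <root>/<case>/<case>_pet.nii.gz        (optional)
    <root>/<case>/<case>_mask.nii.gz

with a ``manifest.json`` at the root listing case ids and modalities.

Preprocessing follows the usual self-configuring-segmentation recipe: crop
to the joint nonzero bounding box, resample to isotropic 1 mm (trilinear for
images, nearest neighbour for the mask), z-score each modality over its
nonzero voxels, and centre pad/crop to a fixed 128^3 grid.  Every step is
recorded so predictions can be mapped back to the native grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np

from .pyramid import Volume, resize_linear3

__all__ = [
    "MODALITY_ORDER",
    "MultimodalCase",
    "PreprocessConfig",
    "InverseRecord",
    "read_nifti",
    "write_nifti",
    "load_case",
    "save_case",
    "load_manifest",
    "write_manifest",
    "preprocess_case",
    "invert_prediction",
    "make_cv_folds",
]

MODALITY_ORDER = ("t1", "flair", "pet")


@dataclass
class MultimodalCase:
    """Co-registered modality volumes + lesion mask + geometry metadata."""

    case_id: str
    volumes: Dict[str, np.ndarray]
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if "t1" not in self.volumes:
            raise ValueError(f"case {self.case_id}: the t1 modality is required")
        shape = self.volumes["t1"].shape
        for name, v in self.volumes.items():
            if v.shape != shape:
                raise ValueError(f"case {self.case_id}: {name} grid {v.shape} != t1 grid {shape}")
        if self.mask.shape != shape:
            raise ValueError(f"case {self.case_id}: mask grid {self.mask.shape} != t1 grid {shape}")
        if not np.all(np.isin(np.unique(self.mask), (0, 1))):
            raise ValueError(f"case {self.case_id}: mask must be binary")

    @property
    def modalities(self) -> List[str]:
        return [m for m in MODALITY_ORDER if m in self.volumes]

    @property
    def shape(self):
        return self.volumes["t1"].shape


@dataclass(frozen=True)
class PreprocessConfig:
    target_spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    target_shape: Tuple[int, int, int] = (128, 128, 128)

    def __post_init__(self):
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target spacing must be positive")
        if any(n % 16 != 0 for n in self.target_shape):
            raise ValueError("target shape must be divisible by 16")


@dataclass
class InverseRecord:
    """Everything needed to map a model-grid prediction back to the native grid."""

    native_shape: Tuple[int, int, int]
    bbox_start: Tuple[int, int, int]
    cropped_shape: Tuple[int, int, int]
    resampled_shape: Tuple[int, int, int]
    place_out: Tuple[slice, ...]  # region of the model grid holding data
    place_in: Tuple[slice, ...]   # corresponding region of the resampled grid


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_nifti(path) -> Tuple[Volume, np.ndarray]:
    """Load a NIfTI file, reoriented to closest-canonical (RAS) axes.

    Returns the volume (values + spacing) and the 4x4 affine.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    values = np.asarray(img.dataobj).astype(np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(values, spacing), np.asarray(img.affine)


def write_nifti(values: np.ndarray, affine: np.ndarray, path, mask: bool = False):
    """Write a volume; masks are stored as unsigned 8-bit integers."""
    data = np.asarray(values)
    data = data.astype(np.uint8) if mask else data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, np.asarray(affine)), str(path))


def save_case(case: MultimodalCase, root) -> Path:
    d = Path(root) / case.case_id
    d.mkdir(parents=True, exist_ok=True)
    for name, vol in case.volumes.items():
        write_nifti(vol, case.affine, d / f"{case.case_id}_{name}.nii.gz")
    write_nifti(case.mask, case.affine, d / f"{case.case_id}_mask.nii.gz", mask=True)
    return d


def load_case(root, case_id: str) -> MultimodalCase:
    d = Path(root) / case_id
    volumes, spacing, affine = {}, (1.0, 1.0, 1.0), np.eye(4)
    for name in MODALITY_ORDER:
        p = d / f"{case_id}_{name}.nii.gz"
        if p.exists():
            vol, affine = read_nifti(p)
            volumes[name] = vol.values
            spacing = vol.spacing
    mask_path = d / f"{case_id}_mask.nii.gz"
    if not mask_path.exists():
        raise FileNotFoundError(f"missing mask for case {case_id}: {mask_path}")
    mask, _ = read_nifti(mask_path)
    return MultimodalCase(case_id, volumes, mask.values.astype(np.uint8),
                          affine=affine, spacing=spacing)


def write_manifest(root, case_ids: Sequence[str], modalities: Sequence[str]):
    manifest = {"cases": list(case_ids), "modalities": list(modalities)}
    with open(Path(root) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_manifest(root) -> dict:
    with open(Path(root) / "manifest.json") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _resize_nearest(x: np.ndarray, target_shape) -> np.ndarray:
    out = x
    for ax, m in zip(range(x.ndim), target_shape):
        n = out.shape[ax]
        if n == m:
            continue
        idx = np.rint(np.linspace(0, n - 1, int(m))).astype(int)
        out = np.take(out, idx, axis=ax)
    return out


def _center_place(src_shape, dst_shape):
    """Slices (dst_region, src_region) centring src inside dst (crop or pad)."""
    dst_sl, src_sl = [], []
    for n, m in zip(src_shape, dst_shape):
        if n <= m:
            off = (m - n) // 2
            dst_sl.append(slice(off, off + n))
            src_sl.append(slice(0, n))
        else:
            off = (n - m) // 2
            dst_sl.append(slice(0, m))
            src_sl.append(slice(off, off + m))
    return tuple(dst_sl), tuple(src_sl)


def preprocess_case(case: MultimodalCase, cfg: PreprocessConfig = PreprocessConfig()):
    """Crop / resample / normalise / pad one case.

    Returns ``(tensor, mask, record)`` where ``tensor`` is float32 of shape
    (n_modalities, *target_shape) in the fixed (t1, flair, pet) channel
    order (absent modalities dropped, t1 always channel 0), ``mask`` is the
    matching uint8 label grid and ``record`` the inverse transform.
    """
    mods = case.modalities
    stack = [np.asarray(case.volumes[m], dtype=np.float64) for m in mods]
    if all(not np.any(v) for v in stack):
        raise ValueError(f"case {case.case_id}: all modalities are empty")

    # 1. joint nonzero bounding box
    support = np.zeros(case.shape, dtype=bool)
    for v in stack:
        support |= v != 0
    nz = np.argwhere(support)
    lo, hi = nz.min(axis=0), nz.max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    stack = [v[box] for v in stack]
    mask = np.asarray(case.mask)[box]
    cropped_shape = stack[0].shape

    # 2. resample to the target spacing
    factors = [s / t for s, t in zip(case.spacing, cfg.target_spacing)]
    res_shape = tuple(max(1, int(round(n * f))) for n, f in zip(cropped_shape, factors))
    if res_shape != cropped_shape:
        stack = [resize_linear3(v, res_shape) for v in stack]
        mask = _resize_nearest(mask, res_shape)

    # 3. per-modality z-score over nonzero voxels (background stays zero)
    norm = []
    for v in stack:
        fg = v != 0
        if fg.any():
            mu, sd = v[fg].mean(), v[fg].std()
            v = np.where(fg, (v - mu) / (sd if sd > 0 else 1.0), 0.0)
        norm.append(v)

    # 4. centre pad / crop to the model grid
    dst_sl, src_sl = _center_place(res_shape, cfg.target_shape)
    tensor = np.zeros((len(mods),) + tuple(cfg.target_shape), dtype=np.float32)
    out_mask = np.zeros(cfg.target_shape, dtype=np.uint8)
    for c, v in enumerate(norm):
        tensor[c][dst_sl] = v[src_sl]
    out_mask[dst_sl] = mask[src_sl]

    record = InverseRecord(
        native_shape=tuple(case.shape),
        bbox_start=tuple(int(a) for a in lo),
        cropped_shape=tuple(cropped_shape),
        resampled_shape=tuple(res_shape),
        place_out=dst_sl,
        place_in=src_sl,
    )
    return tensor, out_mask, record


def invert_prediction(pred: np.ndarray, record: InverseRecord) -> np.ndarray:
    """Map a model-grid binary prediction back to the native grid."""
    res = np.zeros(record.resampled_shape, dtype=np.uint8)
    res[record.place_in] = np.asarray(pred, dtype=np.uint8)[record.place_out]
    if record.resampled_shape != record.cropped_shape:
        res = _resize_nearest(res, record.cropped_shape)
    out = np.zeros(record.native_shape, dtype=np.uint8)
    sl = tuple(slice(a, a + n) for a, n in zip(record.bbox_start, record.cropped_shape))
    out[sl] = res
    return out


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------

def make_cv_folds(case_ids: Sequence[str], k: int = 5, seed: int = 0):
    """Deterministic near-equal k-fold partition.

    Returns a list of k sorted validation-id lists covering all cases.
    """
    ids = list(case_ids)
    if k < 2 or k > len(ids):
        raise ValueError(f"k={k} incompatible with {len(ids)} cases")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(ids[idx])
    return [sorted(f) for f in folds]
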