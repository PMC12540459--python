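"""Lesion segmentation evaluation.

Voxel-overlap metrics (Dice, precision, recall, IoU), the 95th-percentile
Hausdorff distance in millimetres, 26-connectivity cluster statistics
(true-positive / false-positive / false-negative lesions), detection rates
at the Dice thresholds 0.0 ("one-voxel overlap") and 0.22, and the
DC-guided largest-component post-processing rule.

Empty-mask conventions (chosen so cohort averages are reproducible and
recorded per case): Dice(empty, empty) = 1 (and IoU = 1, preserving the
identity DC = 2*IoU/(1+IoU)); precision and recall with 0/0 denominators
are 0; HD95 is undefined when either mask is empty and such cases are
excluded from cohort averages.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "OverlapMetrics",
    "ClusterStats",
    "DetectionReport",
    "overlap_metrics",
    "hd95",
    "connected_components26",
    "cluster_stats",
    "largest_component_postprocess",
    "detection_rates",
    "slice_dice_scores",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

DETECTION_THRESHOLDS = (0.0, 0.22)


@dataclass(frozen=True)
class OverlapMetrics:
    dc: float
    precision: float
    recall: float
    iou: float
    hd95: Optional[float] = None

    def as_dict(self):
        return asdict(self)


@dataclass(frozen=True)
class ClusterStats:
    tp_lesions: int
    fp_lesions: int
    fn_lesions: int
    gt_lesions: int

    def as_dict(self):
        return asdict(self)


@dataclass(frozen=True)
class DetectionReport:
    """Cohort detection rates (percentages) at each Dice threshold."""

    individual: dict  # threshold -> rate
    slice_rates: Optional[dict] = None  # threshold -> mean rate over the 3 axes
    n_cases: int = 0

    def as_dict(self):
        d = {"n_cases": self.n_cases,
             "individual": {str(k): v for k, v in self.individual.items()}}
        if self.slice_rates is not None:
            d["slice"] = {str(k): v for k, v in self.slice_rates.items()}
        return d


def _as_binary(mask) -> np.ndarray:
    m = np.asarray(mask)
    u = np.unique(m)
    if not np.all(np.isin(u, (0, 1))):
        raise ValueError("mask must be strictly binary (0/1)")
    return m.astype(bool)


def overlap_metrics(G, P) -> OverlapMetrics:
    """Voxel-level Dice, precision, recall and IoU of prediction P against
    ground truth G."""
    G, P = _as_binary(G), _as_binary(P)
    if G.shape != P.shape:
        raise ValueError(f"shape mismatch: {G.shape} vs {P.shape}")
    tp = int(np.count_nonzero(G & P))
    fp = int(np.count_nonzero(~G & P))
    fn = int(np.count_nonzero(G & ~P))
    union = tp + fp + fn
    dc = 1.0 if (tp + fp + fn) == 0 else 2.0 * tp / (2 * tp + fp + fn)
    pre = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    rec = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    iou = 1.0 if union == 0 else tp / union
    return OverlapMetrics(dc, pre, rec, iou)


def hd95(G, P, spacing=(1.0, 1.0, 1.0)) -> Optional[float]:
    """95th-percentile symmetric Hausdorff distance in mm over all foreground
    voxel centres: max of the two directed 95th percentiles of
    nearest-neighbour distances.  ``None`` if either mask is empty."""
    G, P = _as_binary(G), _as_binary(P)
    if G.shape != P.shape:
        raise ValueError(f"shape mismatch: {G.shape} vs {P.shape}")
    if not G.any() or not P.any():
        return None
    sp = np.asarray(spacing, dtype=float)
    a = np.argwhere(G) * sp
    b = np.argwhere(P) * sp
    d_ab = cKDTree(b).query(a, k=1)[0]
    d_ba = cKDTree(a).query(b, k=1)[0]
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def connected_components26(mask):
    """Label maximal 26-connected foreground components.

    Returns (labels, n_components); voxels sharing a face, edge or corner
    belong to the same component.
    """
    labels, n = ndimage.label(_as_binary(mask), structure=_STRUCT26)
    return labels, int(n)


def cluster_stats(G, P) -> ClusterStats:
    """Lesion-level counts: a GT component with any predicted overlap is a
    TP lesion, one with none is FN; a predicted component with no GT overlap
    is an FP lesion."""
    G, P = _as_binary(G), _as_binary(P)
    g_lab, g_n = connected_components26(G)
    p_lab, p_n = connected_components26(P)
    fn = sum(1 for i in range(1, g_n + 1) if not P[g_lab == i].any())
    fp = sum(1 for i in range(1, p_n + 1) if not G[p_lab == i].any())
    return ClusterStats(tp_lesions=g_n - fn, fp_lesions=fp, fn_lesions=fn, gt_lesions=g_n)


def largest_component_postprocess(P, G):
    """Keep only the largest 26-connected predicted component if (and only
    if) that strictly improves the Dice against G; otherwise return P
    unchanged.  Ties on component size are broken by the lowest label."""
    P = _as_binary(P)
    G = _as_binary(G)
    labels, n = connected_components26(P)
    if n <= 1:
        return P.astype(np.uint8)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1  # argmax returns the first (lowest) maximiser
    candidate = labels == keep
    if overlap_metrics(G, candidate).dc > overlap_metrics(G, P).dc:
        return candidate.astype(np.uint8)
    return P.astype(np.uint8)


def slice_dice_scores(G, P):
    """Per-axis 2D Dice scores of every ground-truth-bearing slice.

    Returns {axis: list of Dice values}, one value per slice along that axis
    that contains ground-truth foreground.
    """
    G, P = _as_binary(G), _as_binary(P)
    out = {}
    for axis in range(3):
        scores = []
        for idx in range(G.shape[axis]):
            g2 = np.take(G, idx, axis=axis)
            if not g2.any():
                continue
            p2 = np.take(P, idx, axis=axis)
            tp = np.count_nonzero(g2 & p2)
            scores.append(2.0 * tp / (np.count_nonzero(g2) + np.count_nonzero(p2)))
        out[axis] = scores
    return out


def detection_rates(case_dcs: Sequence[float], slice_dcs=None,
                    thresholds=DETECTION_THRESHOLDS) -> DetectionReport:
    """Cohort detection rates: 100 * N_d / N_a where N_d counts cases with
    Dice strictly above the threshold.

    ``slice_dcs`` (optional) is a list of per-case {axis: [slice Dice]}
    dicts (see :func:`slice_dice_scores`); the slice rate at a threshold is
    the detected fraction of GT-bearing slices per axis, pooled over cases,
    averaged unweighted over the three axes.
    """
    case_dcs = list(case_dcs)
    if not case_dcs:
        raise ValueError("detection rate undefined for an empty cohort")
    individual = {
        thr: 100.0 * sum(dc > thr for dc in case_dcs) / len(case_dcs)
        for thr in thresholds
    }
    slice_rates = None
    if slice_dcs is not None:
        slice_rates = {}
        for thr in thresholds:
            per_axis = []
            for axis in range(3):
                pooled = [s for case in slice_dcs for s in case.get(axis, [])]
                if pooled:
                    per_axis.append(100.0 * sum(s > thr for s in pooled) / len(pooled))
            slice_rates[thr] = float(np.mean(per_axis)) if per_axis else float("nan")
    return DetectionReport(individual=individual, slice_rates=slice_rates,
                           n_cases=len(case_dcs))
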