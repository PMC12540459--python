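"""Cohort evaluation reports.

Per-case overlap metrics + cluster statistics as a table (CSV), cohort
summary (means +/- sd, lesion-count totals, detection rates at Dice
thresholds 0.0 and 0.22) as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .metrics import (
    DETECTION_THRESHOLDS,
    cluster_stats,
    detection_rates,
    hd95,
    overlap_metrics,
    slice_dice_scores,
)

__all__ = ["evaluate_case", "evaluate_cohort", "write_report"]


def evaluate_case(case_id: str, G, P, spacing=(1.0, 1.0, 1.0)) -> dict:
    om = overlap_metrics(G, P)
    cs = cluster_stats(G, P)
    return {
        "case_id": case_id,
        "dc": om.dc,
        "precision": om.precision,
        "recall": om.recall,
        "iou": om.iou,
        "hd95": hd95(G, P, spacing),
        **cs.as_dict(),
    }


def evaluate_cohort(cases: Sequence[Tuple[str, np.ndarray, np.ndarray]],
                    spacing=(1.0, 1.0, 1.0), with_slices: bool = True):
    """``cases``: (case_id, ground truth, prediction) triples on a shared
    grid.  Returns (per-case DataFrame, cohort summary dict)."""
    rows = [evaluate_case(cid, G, P, spacing) for cid, G, P in cases]
    df = pd.DataFrame(rows)
    slice_dcs = [slice_dice_scores(G, P) for _, G, P in cases] if with_slices else None
    report = detection_rates(df["dc"].tolist(), slice_dcs)

    hd = df["hd95"].dropna()
    summary = {
        "n_cases": len(df),
        "mean": {m: float(df[m].mean()) for m in ("dc", "precision", "recall", "iou")},
        "sd": {m: float(df[m].std(ddof=0)) for m in ("dc", "precision", "recall", "iou")},
        "hd95_mean": float(hd.mean()) if len(hd) else None,
        "hd95_sd": float(hd.std(ddof=0)) if len(hd) else None,
        "hd95_defined_cases": int(len(hd)),
        "lesions": {k: int(df[k].sum())
                    for k in ("tp_lesions", "fp_lesions", "fn_lesions", "gt_lesions")},
        "detection": report.as_dict(),
    }
    return df, summary


def write_report(df: pd.DataFrame, summary: dict, out_prefix) -> Tuple[Path, Path]:
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = out_prefix.with_suffix(".csv")
    json_path = out_prefix.with_suffix(".json")
    df.to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    return csv_path, json_path
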