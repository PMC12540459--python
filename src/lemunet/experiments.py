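"""Scaled-down reproducibility experiments.

CPU-sized, fully seeded experiments exercising the whole pipeline
(synthesis -> preprocessing -> training -> evaluation).  They are used by
the test suite and the reproduction script; the problem sizes are chosen so
each experiment runs in minutes on a single core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import PreprocessConfig, preprocess_case
from .metrics import overlap_metrics
from .synthetic import SyntheticParams, generate_synthetic_case
from .train import TrainConfig, build_model, predict_case, train_model

__all__ = ["OverfitResult", "overfit_single_case"]


@dataclass(frozen=True)
class OverfitResult:
    seed: int
    train_dc: float
    steps_used: int
    final_loss: float

    @property
    def passed(self) -> bool:
        return self.train_dc > 0.9


def overfit_single_case(
    seed: int,
    grid: int = 32,
    base_channels: int = 8,
    max_steps: int = 300,
    eval_every: int = 50,
    target_dc: float = 0.9,
    lr: float = 1e-3,
) -> OverfitResult:
    """Fit a reduced model (one block per stage) to one synthetic case.

    A sanity check that the full network can learn: on a single 32^3 phantom
    the training Dice should exceed ``target_dc`` well within ``max_steps``
    AdamW steps.  Training stops early once the target is reached (the Dice
    is evaluated every ``eval_every`` steps).
    """
    case = generate_synthetic_case(
        SyntheticParams(shape=(grid,) * 3, semiaxes_range=(3.0, 5.0), seed=seed))
    tensor, mask, _ = preprocess_case(case, PreprocessConfig(target_shape=(grid,) * 3))
    items = [(tensor, mask.astype(np.int64))]

    cfg = TrainConfig(size="tiny", base_channels=base_channels, batch_size=1, lr=lr,
                      max_steps=max_steps, max_epochs=10**9, seed=seed)
    model, params = build_model(cfg)

    state = {"steps": max_steps}

    def reached_target(step, p):
        dc = overlap_metrics(mask > 0, predict_case(model, p, tensor)).dc
        if dc > target_dc:
            state["steps"] = step
            return True
        return False

    params, hist = train_model(model, params, items, cfg,
                               callback=reached_target, callback_every=eval_every)
    dc = overlap_metrics(mask > 0, predict_case(model, params, tensor)).dc
    return OverfitResult(seed=seed, train_dc=float(dc),
                         steps_used=min(state["steps"], len(hist["loss"])),
                         final_loss=float(hist["loss"][-1]))
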