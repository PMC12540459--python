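"""Deep-supervision composite loss.

The training loss is a weighted sum over supervised decoder levels::

    L = sum_i  w_dice^i * L_Dice(f_DS^i, f^i)  +  w_ce^i * L_CE(f_DS^i, f^i)

where f_DS^i is the level-i class-probability map and f^i the ground truth
downsampled (nearest neighbour) to that level.  The soft Dice uses the
squared-denominator form 2*G.P / (G^2 + P^2) with a small smoothing term in
numerator and denominator; the cross entropy is the mean voxel-wise negative
log-likelihood.  Unless stated otherwise the level weights halve with depth
(w_i proportional to 2^-(i-1), normalised to sum 1) and the Dice and CE
weights coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .backbone import SegmentationOutput

__all__ = [
    "LossWeights",
    "default_loss_weights",
    "downsample_gt",
    "soft_dice_loss",
    "cross_entropy_loss",
    "combined_loss",
]

_SMOOTH = 1e-5


@dataclass(frozen=True)
class LossWeights:
    w_dice: tuple
    w_ce: tuple

    def __post_init__(self):
        if len(self.w_dice) != len(self.w_ce):
            raise ValueError("w_dice and w_ce must have the same length")
        if any(w < 0 for w in self.w_dice + self.w_ce):
            raise ValueError("loss weights must be non-negative")

    @property
    def levels(self):
        return len(self.w_dice)


def default_loss_weights(levels: int) -> LossWeights:
    """Halving weights, normalised to sum one, shared by Dice and CE."""
    w = np.array([2.0 ** -(i) for i in range(levels)])
    w = tuple(w / w.sum())
    return LossWeights(w, w)


def downsample_gt(gt: np.ndarray, level: int) -> np.ndarray:
    """Nearest-neighbour label downsampling by 2^(level-1) (level 1 = identity),
    aligned with the network's stride-2 convention (keeps voxels 0, 2, 4...)."""
    if level < 1:
        raise ValueError("level must be >= 1")
    s = 2 ** (level - 1)
    return gt[..., ::s, ::s, ::s]


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, D, H, W) int labels -> (N, n_classes, D, H, W) float32."""
    eye = np.eye(n_classes, dtype=np.float32)
    return np.moveaxis(eye[labels.astype(np.int64)], -1, 1)


def soft_dice_loss(probs, onehot) -> float:
    """1 - soft Dice, averaged over foreground classes.

    Soft Dice per class: (2 * sum(p*g) + s) / (sum(p^2) + sum(g^2) + s);
    for exactly binary probabilities this reduces to the voxel-count Dice.
    """
    axes = (0, 2, 3, 4)
    num = 2.0 * anp.sum(probs * onehot, axis=axes) + _SMOOTH
    den = anp.sum(probs**2, axis=axes) + anp.sum(onehot**2, axis=axes) + _SMOOTH
    dice = num / den
    return 1.0 - anp.mean(dice[1:])


def cross_entropy_loss(probs, onehot) -> float:
    """Mean voxel-wise cross entropy against the one-hot ground truth."""
    return -anp.mean(anp.sum(onehot * anp.log(probs + 1e-12), axis=1))


def combined_loss(outputs: SegmentationOutput, gt: np.ndarray, weights: LossWeights):
    """Deep-supervision Dice + cross-entropy loss.

    ``gt`` is an integer label grid (N, D, H, W) (or (D, H, W) for a single
    case) at full resolution; it is downsampled per level.
    """
    ds = outputs.ds_outputs if isinstance(outputs, SegmentationOutput) else list(outputs)
    if weights.levels != len(ds):
        raise ValueError(f"{weights.levels} weight pairs for {len(ds)} supervised levels")
    gt = np.asarray(gt)
    if gt.ndim == 3:
        gt = gt[None]
    n_classes = ds[0].shape[1]
    total = 0.0
    for i, probs in enumerate(ds):
        wi_d, wi_c = weights.w_dice[i], weights.w_ce[i]
        if wi_d == 0.0 and wi_c == 0.0:
            continue
        gt_i = downsample_gt(gt, i + 1)
        if gt_i.shape[-3:] != probs.shape[-3:]:
            raise ValueError(
                f"level {i + 1}: ground truth grid {gt_i.shape[-3:]} does not "
                f"match prediction grid {probs.shape[-3:]}"
            )
        onehot = _one_hot(gt_i, n_classes)
        total = total + wi_d * soft_dice_loss(probs, onehot) + wi_c * cross_entropy_loss(probs, onehot)
    return total
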