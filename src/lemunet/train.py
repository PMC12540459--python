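"""Training loop, checkpointing and prediction.

Whole-volume training with AdamW on the deep-supervision Dice +
cross-entropy loss.  Runs are fully seeded: parameter initialisation, data
order and (absent) augmentation are all driven by the configured seed, so a
run is reproducible bit-for-bit on the same machine.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from autograd import value_and_grad

from .backbone import BackboneConfig, mednext_l, mednext_m, mednext_tiny
from .edge_attention import LEAConfig
from .fusion import LEMUNet, build_lemunet
from .losses import LossWeights, combined_loss, default_loss_weights
from .metrics import largest_component_postprocess, overlap_metrics
from .nn import AdamW, tree_leaves
from .nn.core import tree_map

__all__ = [
    "TrainConfig",
    "config_from_size",
    "train_model",
    "predict_case",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    size: str = "M"              # M | L | tiny
    kernel: int = 3
    in_channels: int = 3
    classes: int = 2
    base_channels: int = 8       # used by the tiny size only
    batch_size: int = 2
    lr: float = 1e-3
    max_epochs: int = 100
    max_steps: Optional[int] = None
    optimizer: str = "adamw"
    lambda_init: float = 0.5
    weight_decay: float = 0.01
    seed: int = 0
    fold: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.size not in ("M", "L", "tiny"):
            raise ValueError("size must be M, L or tiny")
        if self.batch_size < 1 or self.lr <= 0:
            raise ValueError("batch_size must be >= 1 and lr > 0")
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported")


def config_from_size(cfg: TrainConfig) -> BackboneConfig:
    if cfg.size == "M":
        return mednext_m(cfg.in_channels, cfg.classes)
    if cfg.size == "L":
        return mednext_l(cfg.in_channels, cfg.classes)
    return mednext_tiny(cfg.in_channels, cfg.classes, base_channels=cfg.base_channels)


def build_model(cfg: TrainConfig) -> Tuple[LEMUNet, dict]:
    return build_lemunet(config_from_size(cfg), LEAConfig(lambda_init=cfg.lambda_init),
                         seed=cfg.seed)


def _train_dice(model, params, items) -> float:
    scores = []
    for x, gt in items:
        pred = predict_case(model, params, x)
        scores.append(overlap_metrics(np.asarray(gt) > 0, pred).dc)
    return float(np.mean(scores))


def train_model(
    model: LEMUNet,
    params: dict,
    items: Sequence[Tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    weights: Optional[LossWeights] = None,
    val_items: Optional[Sequence] = None,
    log: Callable[[str], None] = lambda s: None,
    callback: Optional[Callable[[int, dict], bool]] = None,
    callback_every: int = 50,
):
    """Optimise ``params`` on (tensor, label-grid) pairs.

    Stops after ``cfg.max_steps`` optimiser steps if set, else after
    ``cfg.max_epochs`` passes over the items.  ``callback(step, params)``,
    if given, runs every ``callback_every`` steps and stops training early
    when it returns True.  Returns ``(params, history)`` where history
    records per-step losses and, when ``val_items`` is given, per-epoch
    validation Dice.
    """
    weights = weights or default_loss_weights(model.cfg.ds_levels)
    opt = AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history = {"loss": [], "val_dc": [], "train_dc": []}

    def batch_loss(p, xb, gb):
        return combined_loss(model(p, xb), gb, weights)

    vg = value_and_grad(batch_loss)
    step = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(items))
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb = np.stack([items[i][0] for i in sel])
            gb = np.stack([items[i][1] for i in sel])
            loss, grads = vg(params, xb, gb)
            params = opt.step(params, grads)
            history["loss"].append(float(loss))
            step += 1
            if step % 25 == 0:
                log(f"step {step}: loss {loss:.4f}")
            stop = callback is not None and step % callback_every == 0 \
                and callback(step, params)
            if stop or (cfg.max_steps is not None and step >= cfg.max_steps):
                history["train_dc"].append(_train_dice(model, params, items))
                return params, history
        if val_items:
            history["val_dc"].append(_train_dice(model, params, val_items))
            log(f"epoch {epoch + 1}: val DC {history['val_dc'][-1]:.4f}")
    history["train_dc"].append(_train_dice(model, params, items))
    return params, history


def predict_case(model, params, tensor: np.ndarray, postprocess_against=None) -> np.ndarray:
    """Argmax of the full-resolution head for one case tensor (C, D, H, W).

    ``postprocess_against``: optional ground truth enabling the DC-guided
    largest-component rule.
    """
    out = model(params, np.asarray(tensor, dtype=np.float32)[None])
    pred = np.argmax(out.full[0], axis=0).astype(np.uint8)
    if postprocess_against is not None:
        pred = largest_component_postprocess(pred, postprocess_against)
    return pred


# ---------------------------------------------------------------------------
# checkpoints: one .npz of named leaves + a JSON-encoded meta entry
# ---------------------------------------------------------------------------

_CKPT_VERSION = 1


def save_checkpoint(path, params: dict, meta: Optional[dict] = None):
    leaves = {f"p:{k}": v for k, v in tree_leaves(params)}
    header = json.dumps({"version": _CKPT_VERSION, "meta": meta or {}})
    np.savez(str(path), __header__=np.frombuffer(header.encode(), dtype=np.uint8), **leaves)


def load_checkpoint(path, template: dict):
    """Fill a parameter pytree of the template's structure from a checkpoint."""
    with np.load(str(path)) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("version") != _CKPT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {header.get('version')}")
        flat = {k[2:]: data[k] for k in data.files if k.startswith("p:")}

    params = tree_map(np.copy, template)

    def fill(node, prefix=""):
        if isinstance(node, dict):
            for k in node:
                node[k] = fill(node[k], f"{prefix}{k}/")
            return node
        if isinstance(node, list):
            for i in range(len(node)):
                node[i] = fill(node[i], f"{prefix}{i}/")
            return node
        key = prefix[:-1]
        if key not in flat:
            raise KeyError(f"checkpoint missing parameter {key}")
        leaf = flat[key]
        if leaf.shape != np.shape(node):
            raise ValueError(f"checkpoint shape mismatch at {key}")
        return leaf

    return fill(params), header["meta"]
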