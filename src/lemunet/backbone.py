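"""MedNeXt-style 3D encoder-decoder backbone.

The backbone is a ConvNeXt-flavoured U-Net: a 1x1x1 stem, four encoder
stages of residual blocks with 2x down blocks between them, a bottleneck,
and a mirrored decoder with 2x up blocks, additive skip connections and a
softmax head per supervised resolution.

Each block is an inverted-bottleneck residual unit::

    x + Conv_1x1(GELU(Conv_1x1(Norm(DWConv_kxkxk(x)))))

where the depthwise convolution is grouped per channel, the normalisation
is group norm with one group per channel, and the middle 1x1x1 convolution
expands the width by the stage's expansion ratio R.  Down blocks use a
stride-2 depthwise convolution and a stride-2 1x1x1 residual projection to
double the channels; up blocks use transposed convolutions and halve them.

The stage widths are C, 2C, 4C, 8C with a 16C bottleneck.  Two named size
configurations are provided (M and L, both with C = 32) plus a tiny config
for fast experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .nn import (
    ChannelNorm,
    DWConv3d,
    DWConvTranspose3d,
    Module,
    PWConv3d,
    PWConvTranspose3d,
    count_parameters,
    init_tree,
)
from .nn.ops import gelu, softmax_channels

__all__ = [
    "BackboneConfig",
    "SegmentationOutput",
    "MedNeXtBlock",
    "MedNeXtDownBlock",
    "MedNeXtUpBlock",
    "MedNeXtBackbone",
    "build_backbone",
    "count_parameters",
    "mednext_m",
    "mednext_l",
    "mednext_tiny",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Size configuration of the backbone.

    ``block_counts`` and ``expansion_ratios`` have nine entries each:
    four encoder stages, the bottleneck, and four decoder stages (in
    execution order).
    """

    base_channels: int = 32
    kernel_size: int = 3
    block_counts: tuple = (3, 4, 4, 4, 4, 4, 4, 4, 3)
    expansion_ratios: tuple = (2, 3, 4, 4, 4, 4, 4, 3, 2)
    in_channels: int = 1
    out_classes: int = 2
    ds_levels: int = 5

    def __post_init__(self):
        if len(self.block_counts) != 9 or len(self.expansion_ratios) != 9:
            raise ValueError("block_counts and expansion_ratios must have 9 entries")
        if any(b < 1 for b in self.block_counts) or any(r < 1 for r in self.expansion_ratios):
            raise ValueError("block counts and expansion ratios must be >= 1")
        if self.base_channels < 1 or self.in_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.out_classes < 2:
            raise ValueError("out_classes must be >= 2")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if not (1 <= self.ds_levels <= 5):
            raise ValueError("ds_levels must be in 1..5")


def mednext_m(in_channels: int = 1, out_classes: int = 2, ds_levels: int = 5) -> BackboneConfig:
    """The M size (C=32, kernel 3)."""
    return BackboneConfig(32, 3, (3, 4, 4, 4, 4, 4, 4, 4, 3), (2, 3, 4, 4, 4, 4, 4, 3, 2),
                          in_channels, out_classes, ds_levels)


def mednext_l(in_channels: int = 1, out_classes: int = 2, ds_levels: int = 5) -> BackboneConfig:
    """The L size (C=32, kernel 3, deeper and wider expansions)."""
    return BackboneConfig(32, 3, (3, 4, 8, 8, 8, 8, 8, 4, 3), (3, 4, 8, 8, 8, 8, 8, 4, 3),
                          in_channels, out_classes, ds_levels)


def mednext_tiny(in_channels: int = 1, out_classes: int = 2, base_channels: int = 8,
                 ds_levels: int = 5) -> BackboneConfig:
    """A reduced configuration (one block per stage) for CPU-scale runs."""
    return BackboneConfig(base_channels, 3, (1,) * 9, (2,) * 9, in_channels, out_classes, ds_levels)


@dataclass
class SegmentationOutput:
    """Per-deep-supervision-level class probability maps, full resolution
    first; level i lives on the full grid divided by 2^(i-1)."""

    ds_outputs: list

    def __len__(self):
        return len(self.ds_outputs)

    @property
    def full(self):
        return self.ds_outputs[0]


class Sequential(Module):
    def __init__(self, modules):
        self.modules = list(modules)

    def init(self, rng):
        return [m.init(rng) for m in self.modules]

    def __call__(self, params, x):
        for p, m in zip(params, self.modules):
            x = m(p, x)
        return x


class MedNeXtBlock(Module):
    """Residual inverted-bottleneck block (width preserved)."""

    def __init__(self, channels: int, expansion: int, kernel: int = 3):
        self.channels = channels
        self.conv1 = DWConv3d(channels, kernel)
        self.norm = ChannelNorm(channels)
        self.conv2 = PWConv3d(channels, expansion * channels)
        self.conv3 = PWConv3d(expansion * channels, channels)

    def init(self, rng):
        return {"conv1": self.conv1.init(rng), "norm": self.norm.init(rng),
                "conv2": self.conv2.init(rng), "conv3": self.conv3.init(rng)}

    def __call__(self, params, x):
        if x.shape[1] != self.channels:
            raise ValueError(f"block expects {self.channels} channels, got {x.shape[1]}")
        h = self.conv1(params["conv1"], x)
        h = self.conv2(params["conv2"], self.norm(params["norm"], h))
        h = self.conv3(params["conv3"], gelu(h))
        return x + h


class MedNeXtDownBlock(Module):
    """2x down block: stride-2 depthwise conv path plus a stride-2 1x1x1
    residual projection; doubles the channel count."""

    def __init__(self, channels: int, expansion: int, kernel: int = 3):
        self.channels = channels
        self.conv1 = DWConv3d(channels, kernel, stride=2)
        self.norm = ChannelNorm(channels)
        self.conv2 = PWConv3d(channels, expansion * channels)
        self.conv3 = PWConv3d(expansion * channels, 2 * channels)
        self.res = PWConv3d(channels, 2 * channels, stride=2)

    def init(self, rng):
        return {"conv1": self.conv1.init(rng), "norm": self.norm.init(rng),
                "conv2": self.conv2.init(rng), "conv3": self.conv3.init(rng),
                "res": self.res.init(rng)}

    def __call__(self, params, x):
        h = self.conv1(params["conv1"], x)
        h = self.conv2(params["conv2"], self.norm(params["norm"], h))
        h = self.conv3(params["conv3"], gelu(h))
        return h + self.res(params["res"], x)


class MedNeXtUpBlock(Module):
    """2x up block: transposed depthwise conv path plus a transposed 1x1x1
    residual projection; halves the channel count."""

    def __init__(self, channels: int, expansion: int, kernel: int = 3):
        self.channels = channels
        self.conv1 = DWConvTranspose3d(channels, kernel)
        self.norm = ChannelNorm(channels)
        self.conv2 = PWConv3d(channels, expansion * channels)
        self.conv3 = PWConv3d(expansion * channels, channels // 2)
        self.res = PWConvTranspose3d(channels, channels // 2)

    def init(self, rng):
        return {"conv1": self.conv1.init(rng), "norm": self.norm.init(rng),
                "conv2": self.conv2.init(rng), "conv3": self.conv3.init(rng),
                "res": self.res.init(rng)}

    def __call__(self, params, x):
        h = self.conv1(params["conv1"], x)
        h = self.conv2(params["conv2"], self.norm(params["norm"], h))
        h = self.conv3(params["conv3"], gelu(h))
        return h + self.res(params["res"], x)


class MedNeXtBackbone(Module):
    """Encoder-decoder with deep supervision.

    ``encode`` exposes the per-stage encoder features (f_e^1 at full
    resolution with C channels, f_e^2 at half resolution with 2C, ...);
    ``decode`` accepts optional extra feature maps to be added to the
    decoder features f_d^2 and f_d^1 (the fusion hook used by the full
    edge-guided model).
    """

    def __init__(self, cfg: BackboneConfig):
        self.cfg = cfg
        C, k = cfg.base_channels, cfg.kernel_size
        B, R = cfg.block_counts, cfg.expansion_ratios
        widths = [C, 2 * C, 4 * C, 8 * C, 16 * C]
        self.widths = widths

        self.stem = PWConv3d(cfg.in_channels, C)
        self.enc = [Sequential([MedNeXtBlock(widths[s], R[s], k) for _ in range(B[s])])
                    for s in range(4)]
        self.down = [MedNeXtDownBlock(widths[s], R[s + 1], k) for s in range(4)]
        self.bottleneck = Sequential([MedNeXtBlock(widths[4], R[4], k) for _ in range(B[4])])
        self.up = [MedNeXtUpBlock(widths[s + 1], R[8 - s], k) for s in range(3, -1, -1)]
        self.dec = [Sequential([MedNeXtBlock(widths[s], R[8 - s], k) for _ in range(B[8 - s])])
                    for s in range(3, -1, -1)]
        # heads: level 1 on the final decoder output (width C), deeper levels
        # on decoder stage outputs / the bottleneck
        head_widths = [C, 2 * C, 4 * C, 8 * C, 16 * C][: cfg.ds_levels]
        self.heads = [PWConv3d(w, cfg.out_classes) for w in head_widths]

    # -- parameters ---------------------------------------------------------

    def init(self, rng: np.random.Generator) -> dict:
        return {
            "stem": self.stem.init(rng),
            "enc": [m.init(rng) for m in self.enc],
            "down": [m.init(rng) for m in self.down],
            "bottleneck": self.bottleneck.init(rng),
            "up": [m.init(rng) for m in self.up],
            "dec": [m.init(rng) for m in self.dec],
            "heads": [m.init(rng) for m in self.heads],
        }

    # -- forward ------------------------------------------------------------

    def _check_grid(self, x):
        if x.ndim != 5:
            raise ValueError(f"expected (N, C, D, H, W) input, got shape {x.shape}")
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        if any(n % 16 != 0 for n in x.shape[2:]):
            raise ValueError(f"spatial grid {x.shape[2:]} must be divisible by 16")

    def encode(self, params, x):
        """Return (skips, bottom): four per-stage features plus the
        bottleneck output.  skips[0] is f_e^1, skips[1] is f_e^2."""
        self._check_grid(x)
        h = self.stem(params["stem"], x)
        skips = []
        for s in range(4):
            h = self.enc[s](params["enc"][s], h)
            skips.append(h)
            h = self.down[s](params["down"][s], h)
        bottom = self.bottleneck(params["bottleneck"], h)
        return skips, bottom

    def decode(self, params, skips, bottom, extras=None) -> SegmentationOutput:
        """Decoder with optional additive fusion.

        ``extras`` maps decoder level i (1 = full resolution, 2 = half) to a
        feature map added to f_d^i (the post-skip upsampling result) before
        that stage's blocks.
        """
        extras = extras or {}
        D = self.cfg.ds_levels
        logits = [None] * D
        if D >= 5:
            logits[4] = self.heads[4](params["heads"][4], bottom)
        h = bottom
        for idx, s in enumerate(range(3, -1, -1)):  # s: encoder stage of the skip
            h = self.up[idx](params["up"][idx], h)
            h = h + skips[s]
            level = s + 1  # 1-based decoder level by resolution
            extra = extras.get(level)
            if callable(extra):
                extra = extra(level, h)
            if extra is not None:
                h = h + extra
            h = self.dec[idx](params["dec"][idx], h)
            if level <= D:
                logits[level - 1] = self.heads[level - 1](params["heads"][level - 1], h)
        return SegmentationOutput([softmax_channels(z) for z in logits if z is not None])

    def __call__(self, params, x, extras=None) -> SegmentationOutput:
        skips, bottom = self.encode(params, x)
        return self.decode(params, skips, bottom, extras=extras)


def build_backbone(cfg: BackboneConfig, seed: int = 0):
    """Construct a backbone and its parameter pytree (deterministic per seed)."""
    model = MedNeXtBackbone(cfg)
    params = model.init(np.random.default_rng(seed))
    return model, params
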