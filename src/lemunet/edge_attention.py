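"""Laplacian edge attention (LEA).

Each LEA block sits behind one of the first two encoder stages and receives
three inputs: the main-encoder feature f_e^i, the feature f_eT1^i from a
separate encoding branch that sees only the T1 channel, and the level-i
Laplacian-pyramid residual f_l^i of the T1 volume (one channel).

Both encoded features pass through their own CBAM (channel attention then
spatial attention, each a multiplicative gate in (0,1)).  A single learnable
scalar lambda mixes the two gated features (the T1 branch receives weight
beta = 1 - lambda, enforced structurally), followed by batch normalisation::

    f_map = BN(lambda * CBAM(f_e) + (1 - lambda) * CBAM(f_eT1))

The Laplacian residual then gates the mixture: the residual is concatenated
onto f_map, squashed voxel-wise with a sigmoid, and projected back to the
stage width::

    map    = sigmoid(concat[f_l, f_map])            # C+1 channels
    f_edge = GELU(BN(Conv_1x1x1(map)))              # C channels

lambda is stored unconstrained (initialised to 0.5 by default); nothing in
the mixing rule requires it to stay inside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .backbone import BackboneConfig, MedNeXtBlock, MedNeXtDownBlock, Sequential
from .nn import BatchNorm, Conv3d, Linear, Module, PWConv3d
from .nn.core import DTYPE
from .nn.ops import gelu, global_avg_pool, global_max_pool, sigmoid

__all__ = ["LEAConfig", "CBAM", "LEABlock", "T1Branch"]


@dataclass(frozen=True)
class LEAConfig:
    lambda_init: float = 0.5
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7

    def __post_init__(self):
        if not 0.0 <= self.lambda_init <= 1.0:
            raise ValueError("lambda_init must lie in [0, 1]")
        if self.cbam_reduction < 1:
            raise ValueError("cbam_reduction must be >= 1")
        if self.cbam_spatial_kernel % 2 != 1:
            raise ValueError("cbam_spatial_kernel must be odd")


class CBAM(Module):
    """Convolutional block attention: channel gate then spatial gate.

    The channel gate pools the grid globally (average and max), runs both
    pooled vectors through a shared two-layer MLP and gates each channel by
    the sigmoid of their sum.  The spatial gate stacks the channel-wise mean
    and max maps and gates every voxel by the sigmoid of a k^3 convolution
    over them.
    """

    def __init__(self, channels: int, reduction: int = 16, spatial_kernel: int = 7):
        if channels % min(reduction, channels) != 0:
            raise ValueError(f"reduction {reduction} does not divide {channels} channels")
        hidden = max(channels // reduction, 1)
        self.channels = channels
        self.fc1 = Linear(channels, hidden)
        self.fc2 = Linear(hidden, channels)
        self.spatial = Conv3d(2, 1, spatial_kernel)

    def init(self, rng):
        return {"fc1": self.fc1.init(rng), "fc2": self.fc2.init(rng),
                "spatial": self.spatial.init(rng)}

    def __call__(self, params, x):
        if x.shape[1] != self.channels:
            raise ValueError(f"CBAM expects {self.channels} channels, got {x.shape[1]}")

        def mlp(v):
            return self.fc2(params["fc2"], anp.maximum(self.fc1(params["fc1"], v), 0.0))

        ch = sigmoid(mlp(global_avg_pool(x)) + mlp(global_max_pool(x)))
        x = x * ch[:, :, None, None, None]
        stack = anp.stack([anp.mean(x, axis=1), anp.max(x, axis=1)], axis=1)
        sp = sigmoid(self.spatial(params["spatial"], stack))
        return x * sp


class LEABlock(Module):
    """Edge attention for one encoder level of width ``channels``."""

    def __init__(self, channels: int, cfg: LEAConfig = LEAConfig()):
        self.channels = channels
        self.cfg = cfg
        self.cbam_main = CBAM(channels, cfg.cbam_reduction, cfg.cbam_spatial_kernel)
        self.cbam_t1 = CBAM(channels, cfg.cbam_reduction, cfg.cbam_spatial_kernel)
        self.bn_mix = BatchNorm(channels)
        self.edge_conv = PWConv3d(channels + 1, channels)
        self.bn_edge = BatchNorm(channels)

    def init(self, rng):
        return {
            "cbam_main": self.cbam_main.init(rng),
            "cbam_t1": self.cbam_t1.init(rng),
            "lam": np.array(self.cfg.lambda_init, dtype=DTYPE),
            "bn_mix": self.bn_mix.init(rng),
            "edge_conv": self.edge_conv.init(rng),
            "bn_edge": self.bn_edge.init(rng),
        }

    def combine_branches(self, params, fe, fe_t1):
        """BN(lambda * CBAM(f_e) + (1 - lambda) * CBAM(f_eT1))."""
        if fe.shape != fe_t1.shape:
            raise ValueError(f"branch shapes differ: {fe.shape} vs {fe_t1.shape}")
        lam = params["lam"]
        mixed = lam * self.cbam_main(params["cbam_main"], fe) \
            + (1.0 - lam) * self.cbam_t1(params["cbam_t1"], fe_t1)
        return self.bn_mix(params["bn_mix"], mixed)

    def edge_attend(self, params, fl, fmap):
        """sigmoid of the raw concatenation, then 1x1x1 conv + BN + GELU."""
        if fl.shape[1] != 1:
            raise ValueError("Laplacian feature must have exactly one channel")
        if fl.shape[2:] != fmap.shape[2:]:
            raise ValueError(f"resolution mismatch: {fl.shape[2:]} vs {fmap.shape[2:]}")
        gate = sigmoid(anp.concatenate([fl, fmap], axis=1))
        h = self.edge_conv(params["edge_conv"], gate)
        return gelu(self.bn_edge(params["bn_edge"], h))

    def __call__(self, params, fe, fe_t1, fl):
        return self.edge_attend(params, fl, self.combine_branches(params, fe, fe_t1))


class T1Branch(Module):
    """Independent encoding of the T1 channel, mirroring the main encoder's
    first two stages (stem, stage-1 blocks, 2x down, stage-2 blocks) with its
    own parameters."""

    def __init__(self, cfg: BackboneConfig):
        C, k = cfg.base_channels, cfg.kernel_size
        B, R = cfg.block_counts, cfg.expansion_ratios
        self.stem = PWConv3d(1, C)
        self.stage1 = Sequential([MedNeXtBlock(C, R[0], k) for _ in range(B[0])])
        self.down = MedNeXtDownBlock(C, R[1], k)
        self.stage2 = Sequential([MedNeXtBlock(2 * C, R[1], k) for _ in range(B[1])])

    def init(self, rng):
        return {"stem": self.stem.init(rng), "stage1": self.stage1.init(rng),
                "down": self.down.init(rng), "stage2": self.stage2.init(rng)}

    def __call__(self, params, t1):
        """``t1``: (N, 1, D, H, W) -> (f_eT1^1 at CxDxHxW, f_eT1^2 at 2C x half)."""
        if t1.shape[1] != 1:
            raise ValueError("T1 branch consumes a single channel")
        h = self.stage1(params["stage1"], self.stem(params["stem"], t1))
        f1 = h
        f2 = self.stage2(params["stage2"], self.down(params["down"], h))
        return f1, f2
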