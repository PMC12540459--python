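"""Multi-strategy feature fusion (MFF) and the full edge-guided model.

The decoder features f_d^1 (full resolution, C channels — the last
upsampling result) and f_d^2 (half resolution, 2C channels) are fused with
the edge-attention features before each stage's decoder blocks:

* per-channel high-frequency residual of a decoder feature::

      M^i = f_d^i - up(d(gs(f_d^i)))

  (one Laplacian level applied channel-wise; suppresses the low-frequency
  bulk so the gate focuses on detail);

* MFF(1):  f_mff^1 = sigmoid(M^1) * f_edge^1

* MFF(2):  I = sigmoid(Conv_1x1x1(f_edge^2))
           f_mff^2 = sigmoid(M^2) * (f_edge^2 + Conv_1x1x1(d(f_edge^1)) * I)

  where d(f_edge^1) is a plain stride-2 subsampling (no pre-smoothing) and
  the 1x1x1 convolution lifts it from C to 2C channels.

The fused features are added to f_d^i — plain addition, no renormalisation —
so zeroing them recovers the plain backbone exactly.

``LEMUNet`` wires the whole pipeline: Laplacian pyramid of the T1 channel,
the independent T1 encoding branch, LEA at encoder stages 1-2, the backbone
encoder/decoder, and MFF at the last two decoder stages (MFF(2) executes
before MFF(1): the decoder reaches the half-resolution layer first).
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from .backbone import BackboneConfig, MedNeXtBackbone, SegmentationOutput
from .edge_attention import LEABlock, LEAConfig, T1Branch
from .nn import Module, PWConv3d, count_parameters
from .nn.ops import sigmoid
from .pyramid import decimate2, highpass3, smooth3

__all__ = ["highfreq_residual", "MFF2", "LEMUNet", "build_lemunet"]


def highfreq_residual(fd):
    """Per-channel one-level Laplacian residual M = fd - up(d(gs(fd)))."""
    if any(n < 2 for n in fd.shape[-3:]):
        raise ValueError(f"grid {fd.shape[-3:]} too small for a pyramid level")
    return highpass3(fd)


def mff1(fd1, fedge1):
    """Fusion at the final decoder layer: sigmoid(M^1) * f_edge^1."""
    if fd1.shape != fedge1.shape:
        raise ValueError(f"shape mismatch: {fd1.shape} vs {fedge1.shape}")
    return sigmoid(highfreq_residual(fd1)) * fedge1


class MFF2(Module):
    """Fusion at the penultimate decoder layer (Eq. MFF(2) above)."""

    def __init__(self, channels: int):
        # ``channels`` is C (full-resolution width); this block works at 2C
        self.channels = channels
        self.conv_i = PWConv3d(2 * channels, 2 * channels)
        self.bridge = PWConv3d(channels, 2 * channels)

    def init(self, rng):
        return {"conv_i": self.conv_i.init(rng), "bridge": self.bridge.init(rng)}

    def __call__(self, params, fd2, fedge1, fedge2):
        if fd2.shape != fedge2.shape:
            raise ValueError(f"shape mismatch: {fd2.shape} vs {fedge2.shape}")
        if fedge1.shape[1] != self.channels or fedge2.shape[1] != 2 * self.channels:
            raise ValueError("edge features have inconsistent widths")
        down1 = decimate2(fedge1)
        if down1.shape[2:] != fedge2.shape[2:]:
            raise ValueError(
                f"downsampled f_edge^1 grid {down1.shape[2:]} does not match "
                f"f_edge^2 grid {fedge2.shape[2:]}"
            )
        gate_i = sigmoid(self.conv_i(params["conv_i"], fedge2))
        bridge = self.bridge(params["bridge"], down1)
        return sigmoid(highfreq_residual(fd2)) * (fedge2 + bridge * gate_i)


class LEMUNet(Module):
    """Edge-guided multimodal segmentation network.

    Input tensor: (N, in_channels, D, H, W) with the T1 channel at index 0
    and every spatial axis divisible by 16.
    """

    def __init__(self, cfg: BackboneConfig, lea_cfg: LEAConfig = LEAConfig()):
        C = cfg.base_channels
        self.cfg = cfg
        self.lea_cfg = lea_cfg
        self.backbone = MedNeXtBackbone(cfg)
        self.t1_branch = T1Branch(cfg)
        self.lea1 = LEABlock(C, lea_cfg)
        self.lea2 = LEABlock(2 * C, lea_cfg)
        self.mff2 = MFF2(C)

    def init(self, rng: np.random.Generator) -> dict:
        return {
            "backbone": self.backbone.init(rng),
            "t1_branch": self.t1_branch.init(rng),
            "lea1": self.lea1.init(rng),
            "lea2": self.lea2.init(rng),
            "mff2": self.mff2.init(rng),
        }

    @staticmethod
    def laplacian_inputs(t1):
        """First two Laplacian residuals of the (preprocessed) T1 channel:
        f_l^1 at full resolution and f_l^2 at half resolution, one channel."""
        fl1 = highpass3(t1)
        n1 = decimate2(smooth3(t1))
        fl2 = highpass3(n1)
        return fl1, fl2

    def __call__(self, params, x, zero_fusion: bool = False,
                 return_features: bool = False):
        if x.ndim != 5 or x.shape[1] < 1:
            raise ValueError("input must be (N, C>=1, D, H, W) with T1 at channel 0")
        t1 = x[:, 0:1]
        fl1, fl2 = self.laplacian_inputs(np.asarray(t1))

        skips, bottom = self.backbone.encode(params["backbone"], x)
        ft1_1, ft1_2 = self.t1_branch(params["t1_branch"], t1)
        fedge1 = self.lea1(params["lea1"], skips[0], ft1_1, fl1)
        fedge2 = self.lea2(params["lea2"], skips[1], ft1_2, fl2)

        feats = {"fedge1": fedge1, "fedge2": fedge2}

        def fuse(level, fd):
            if level == 2:
                m = self.mff2(params["mff2"], fd, fedge1, fedge2)
            else:
                m = mff1(fd, fedge1)
            if return_features:
                feats[f"fmff{level}"] = m
            return m * 0.0 if zero_fusion else m

        extras = {1: fuse, 2: fuse}
        out = self.backbone.decode(params["backbone"], skips, bottom, extras=extras)
        if return_features:
            return out, feats
        return out


def build_lemunet(cfg: BackboneConfig, lea_cfg: LEAConfig = LEAConfig(), seed: int = 0):
    """Construct the full model and its parameters (deterministic per seed)."""
    model = LEMUNet(cfg, lea_cfg)
    params = model.init(np.random.default_rng(seed))
    return model, params


def lemunet_forward(model: LEMUNet, params, x, **kwargs) -> SegmentationOutput:
    """Functional alias for ``model(params, x)``."""
    return model(params, x, **kwargs)
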