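"""Minimal module system: layers declare their parameters, parameters live
in plain nested dicts, forward passes are pure functions of (params, input).

Keeping parameters outside the module objects lets ``autograd`` differentiate
a whole network as one function of one pytree, and makes checkpoints trivial
(flatten the dict, save the leaves).
"""

from __future__ import annotations

import numpy as np

from . import ops

DTYPE = np.float32


class Module:
    """Base class.  Subclasses implement ``init(rng) -> params`` and
    ``__call__(params, *inputs)``."""

    def init(self, rng: np.random.Generator) -> dict:
        raise NotImplementedError

    def __call__(self, params, *args, **kwargs):
        raise NotImplementedError


def _he_normal(rng, shape, fan_in):
    std = np.sqrt(2.0 / max(fan_in, 1))
    return (rng.standard_normal(shape) * std).astype(DTYPE)


class DWConv3d(Module):
    """Depthwise k^3 convolution (one filter per channel)."""

    def __init__(self, channels: int, kernel: int, stride: int = 1, bias: bool = True):
        self.channels, self.kernel, self.stride, self.bias = channels, kernel, stride, bias

    def init(self, rng):
        p = {"w": _he_normal(rng, (self.channels, self.kernel, self.kernel, self.kernel), self.kernel**3)}
        if self.bias:
            p["b"] = np.zeros(self.channels, dtype=DTYPE)
        return p

    def __call__(self, params, x):
        return ops.dwconv3d(x, params["w"], params.get("b"), self.stride)


class DWConvTranspose3d(Module):
    """Depthwise transposed convolution, stride 2 (exact 2x upsampling)."""

    def __init__(self, channels: int, kernel: int, bias: bool = True):
        self.channels, self.kernel, self.bias = channels, kernel, bias

    def init(self, rng):
        p = {"w": _he_normal(rng, (self.channels, self.kernel, self.kernel, self.kernel), self.kernel**3)}
        if self.bias:
            p["b"] = np.zeros(self.channels, dtype=DTYPE)
        return p

    def __call__(self, params, x):
        return ops.dwconv_transpose3d_s2(x, params["w"], params.get("b"))


class PWConv3d(Module):
    """1x1x1 convolution."""

    def __init__(self, cin: int, cout: int, stride: int = 1, bias: bool = True):
        self.cin, self.cout, self.stride, self.bias = cin, cout, stride, bias

    def init(self, rng):
        p = {"w": _he_normal(rng, (self.cout, self.cin), self.cin)}
        if self.bias:
            p["b"] = np.zeros(self.cout, dtype=DTYPE)
        return p

    def __call__(self, params, x):
        if self.stride > 1:
            x = x[:, :, :: self.stride, :: self.stride, :: self.stride]
        return ops.pwconv3d(x, params["w"], params.get("b"))


class PWConvTranspose3d(Module):
    """1x1x1 transposed convolution, stride 2."""

    def __init__(self, cin: int, cout: int, bias: bool = True):
        self.cin, self.cout, self.bias = cin, cout, bias

    def init(self, rng):
        p = {"w": _he_normal(rng, (self.cout, self.cin), self.cin)}
        if self.bias:
            p["b"] = np.zeros(self.cout, dtype=DTYPE)
        return p

    def __call__(self, params, x):
        return ops.pwconv_transpose3d_s2(x, params["w"], params.get("b"))


class Conv3d(Module):
    """Dense k^3 convolution over all input channels."""

    def __init__(self, cin: int, cout: int, kernel: int, bias: bool = True):
        self.cin, self.cout, self.kernel, self.bias = cin, cout, kernel, bias

    def init(self, rng):
        k = self.kernel
        p = {"w": _he_normal(rng, (self.cout, self.cin, k, k, k), self.cin * k**3)}
        if self.bias:
            p["b"] = np.zeros(self.cout, dtype=DTYPE)
        return p

    def __call__(self, params, x):
        return ops.conv3d(x, params["w"], params.get("b"), 1)


class ChannelNorm(Module):
    """Affine group norm, one group per channel."""

    def __init__(self, channels: int):
        self.channels = channels

    def init(self, rng):
        return {"g": np.ones(self.channels, dtype=DTYPE), "b": np.zeros(self.channels, dtype=DTYPE)}

    def __call__(self, params, x):
        return ops.channel_norm(x, params["g"], params["b"])


class BatchNorm(Module):
    def __init__(self, channels: int):
        self.channels = channels

    def init(self, rng):
        return {"g": np.ones(self.channels, dtype=DTYPE), "b": np.zeros(self.channels, dtype=DTYPE)}

    def __call__(self, params, x):
        return ops.batch_norm(x, params["g"], params["b"])


class Linear(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True):
        self.cin, self.cout, self.bias = cin, cout, bias

    def init(self, rng):
        p = {"w": _he_normal(rng, (self.cout, self.cin), self.cin)}
        if self.bias:
            p["b"] = np.zeros(self.cout, dtype=DTYPE)
        return p

    def __call__(self, params, x):
        y = x @ params["w"].T
        if self.bias:
            y = y + params["b"]
        return y


def init_tree(modules: dict, rng: np.random.Generator) -> dict:
    """Initialise a dict of named (sub)modules in sorted-key order, so the
    parameter vector is a deterministic function of the seed."""
    return {name: modules[name].init(rng) for name in modules}


def count_parameters(params) -> int:
    """Total number of trainable scalars in a parameter pytree."""
    if isinstance(params, dict):
        return sum(count_parameters(v) for v in params.values())
    if isinstance(params, (list, tuple)):
        return sum(count_parameters(v) for v in params)
    return int(np.size(params))


def tree_map(f, tree):
    if isinstance(tree, dict):
        return {k: tree_map(f, v) for k, v in tree.items()}
    if isinstance(tree, (list, tuple)):
        return type(tree)(tree_map(f, v) for v in tree)
    return f(tree)


def tree_leaves(tree, prefix=""):
    """Yield (path, leaf) pairs in deterministic order."""
    if isinstance(tree, dict):
        for k in tree:
            yield from tree_leaves(tree[k], f"{prefix}{k}/")
    elif isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            yield from tree_leaves(v, f"{prefix}{i}/")
    else:
        yield prefix[:-1], tree
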