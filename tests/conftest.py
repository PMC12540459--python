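import numpy as np
import pytest

from lemunet import build_backbone, build_lemunet, mednext_tiny


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cfg():
    return mednext_tiny(in_channels=3, out_classes=2, base_channels=8)


@pytest.fixture(scope="session")
def tiny_backbone(tiny_cfg):
    return build_backbone(tiny_cfg, seed=11)


@pytest.fixture(scope="session")
def tiny_lemunet(tiny_cfg):
    return build_lemunet(tiny_cfg, seed=11)
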