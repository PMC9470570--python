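import numpy as np
import pytest

from endoattn.model import AttentionConfig, BackboneConfig, ChannelPlan
from endoattn.synthetic import FrameSpec, generate_dataset


@pytest.fixture(scope="session")
def small_backbone_cfg() -> BackboneConfig:
    """Desk-scale backbone: 128-px input, reduced channel widths."""
    return BackboneConfig(input_side=128, channel_plan=ChannelPlan.small())


@pytest.fixture(scope="session")
def default_attn_cfg() -> AttentionConfig:
    return AttentionConfig()


@pytest.fixture(scope="session")
def smoke_dataset(tmp_path_factory):
    """16 balanced synthetic frames (8 per class) with ground-truth masks."""
    out = tmp_path_factory.mktemp("smoke_data")
    manifest = generate_dataset((8, 8), FrameSpec(), seed=7, out_dir=out)
    return manifest


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
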