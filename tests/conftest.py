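import numpy as np
import pytest

from uncrowd.capsule_core import NetworkConfig
from uncrowd.stimuli import StimulusConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def stim_cfg():
    return StimulusConfig()


@pytest.fixture
def small_stim_cfg():
    return StimulusConfig.small()


@pytest.fixture
def tiny_net_cfg(small_stim_cfg):
    """A capsule configuration small enough for fast forward passes."""
    return NetworkConfig(
        image_shape=(small_stim_cfg.height, small_stim_cfg.width),
        conv_layers=((3, 8, 2), (3, 8, 2)),
        primary_dim=6,
        secondary_dim=8,
        recon_hidden=(32, 64),
        vernier_decoder_hidden=16,
        routing_iterations=2,
    )
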