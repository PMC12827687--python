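import numpy as np
import pytest

from remap_energy.datasets import WorldConfig, make_datasets
from remap_energy.network import NetworkConfig, init_weights


TINY_WORLD = WorldConfig(side=32, crop_side=16, n_fixations=4, sequences_per_scene=3)
TINY_NET = NetworkConfig(
    crop_side=16, n_hidden_layers=2, hidden_size=32, steps_per_fixation=3, scene_side=32
)


@pytest.fixture(scope="session")
def tiny_data():
    """Small world: 12 train / 4 test scenes of 32 px, 16 px crops."""
    return make_datasets(12, 4, TINY_WORLD, seed=11)


@pytest.fixture(scope="session")
def tiny_net_config():
    return TINY_NET


@pytest.fixture(scope="session")
def tiny_weights(tiny_net_config):
    return init_weights(tiny_net_config, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
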