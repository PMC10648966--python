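import numpy as np
import pytest

from nmrmixid import (
    AugmentConfig,
    PreprocessConfig,
    SimulationConfig,
    make_flavor_library,
    preprocess_library,
)


@pytest.fixture(scope="session")
def small_sim_config():
    """Desk-scale simulation: 6 flavors on a 1024-point grid."""
    return SimulationConfig(n_flavors=6, n_points=1024, seed=11)


@pytest.fixture(scope="session")
def raw_library(small_sim_config):
    return make_flavor_library(small_sim_config)


@pytest.fixture(scope="session")
def processed_library(raw_library):
    return preprocess_library(raw_library, PreprocessConfig())


@pytest.fixture(scope="session")
def augment_config():
    return AugmentConfig(n_pairs=60, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
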