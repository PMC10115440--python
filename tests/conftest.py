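import numpy as np
import pytest

from boutonquant.protocols import default_protocol
from boutonquant.synth import (
    GCAMP6F,
    GeneratorConfig,
    NoiseParams,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def gcamp_protocol():
    return default_protocol("physin-gcamp")


@pytest.fixture(scope="session")
def gcamp_sensor():
    return GCAMP6F


@pytest.fixture(scope="session")
def small_dataset():
    """2 neurons x 40 terminals x 2 conditions, default noise, traces only."""
    cfg = GeneratorConfig(n_neurons=2, n_terminals=40, ca_e_mm=(2.0, 0.8), seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """1 neuron x 60 terminals, zero noise — generator-oracle comparisons."""
    cfg = GeneratorConfig(n_neurons=1, n_terminals=60, ca_e_mm=(2.0, 1.2), seed=5,
                          noise=NoiseParams(read_sd=0.0, shot_scale=0.0))
    return generate_dataset(cfg)
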