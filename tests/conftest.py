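import numpy as np
import pytest

from dyadsync import FOUR_OSC, TWO_OSC, ModelSpec, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def four_spec():
    return ModelSpec(FOUR_OSC, e1=5.0, e2=5.0, i1=2.0, i2=2.0)


@pytest.fixture
def two_spec():
    return ModelSpec(TWO_OSC, e1=3.0, e2=3.0)


@pytest.fixture
def quiet_config():
    """Deterministic config: no noise, no frequency spread."""
    return SimulationConfig(noise_sd=0.0, freq_sd=0.0, seed=0)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=0)
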