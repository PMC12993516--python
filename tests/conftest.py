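import pytest

from rsil import CarbonPool, MicrocosmConfig
from rsil.simulate import SimulationParams


@pytest.fixture
def config():
    return MicrocosmConfig()


@pytest.fixture
def buffer_pool(config):
    return CarbonPool(config.buffer_total_co2, config.buffer_atom_pct)


@pytest.fixture
def noiseless_params():
    return SimulationParams(seed=1, sigma_delta=0.0, replicate_cv=0.0)
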