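import pytest

from fiberatlas.eet_detect import load_table1_fixture
from fiberatlas.synthetic_data import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def table1():
    """The packaged published EET table (62 transcripts, OF/LRS pooled)."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def sim():
    """Default synthetic benchmark at a fixed seed."""
    return simulate_expression(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=1)
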