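import numpy as np
import pytest

from swgshrd import SimulationConfig, reduced_karyotype


@pytest.fixture(scope="session")
def genome():
    return reduced_karyotype()


@pytest.fixture()
def sim_config():
    return SimulationConfig(seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
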