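import numpy as np
import pytest

from irsirna.simdata import SimulationConfig, generate_ir_genome


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_locus(default_config):
    """(genome, features, truth) for the default simulated IR locus."""
    return generate_ir_genome(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
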