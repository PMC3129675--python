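import numpy as np
import pytest

from imprintscan.config import RunConfig
from imprintscan.simulate import SimConfig, simulate_panel


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def default_panel():
    """One default synthetic panel shared by read-only tests."""
    return simulate_panel(SimConfig(rng_seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
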