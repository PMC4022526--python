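import numpy as np
import pytest

from mammosim import default_config, run_replication
from mammosim.fixtures import Fixtures


@pytest.fixture(scope="session")
def small_config():
    """Reduced population for fast unit-level simulation checks."""
    return default_config(scale=0.05)


@pytest.fixture(scope="session")
def small_fixtures(small_config):
    return Fixtures.from_config(small_config)


@pytest.fixture(scope="session")
def small_run(small_config, small_fixtures):
    """One paired replication at parameters fixed to the distribution means."""
    return run_replication(small_config, 1234, fixtures=small_fixtures,
                           psa_mode="mean")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
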