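import numpy as np
import pytest

from ohca_coverage import generate_city, simulate_events, write_fixture_table1


@pytest.fixture(scope="session")
def table1_events():
    return write_fixture_table1()


@pytest.fixture(scope="session")
def city():
    return generate_city(seed=1)


@pytest.fixture(scope="session")
def events(city):
    return simulate_events(city, 476, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
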