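import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from miisr import LocalizationTable

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
    deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """5 molecules with full metadata, hand-placed for exact oracles."""
    return LocalizationTable(
        x=[0.0, 100.0, 100.0, 500.0, 950.0],
        y=[0.0, 0.0, 100.0, 500.0, 950.0],
        photons=[100, 200, 300, 400, 500],
        precision=[10.0, 12.0, 8.0, 15.0, 11.0],
        channel_id="fix",
    )


@pytest.fixture
def uniform_table(rng):
    """1000 uniform molecules in a 2000x2000 nm square."""
    return LocalizationTable(
        x=rng.uniform(0, 2000, 1000),
        y=rng.uniform(0, 2000, 1000),
        channel_id="uniform",
    )


def make_uniform(n, extent, rng, channel_id="u"):
    return LocalizationTable(
        x=rng.uniform(0, extent, n),
        y=rng.uniform(0, extent, n),
        channel_id=channel_id,
    )
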