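import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thinktime import SimConfig, TimeControl, generate_dataset, make_fixture_positions

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_sets():
    return make_fixture_positions()


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-game simulated dataset under the default power-cost policy."""
    cfg = SimConfig(n_games=300, seed=42, compute_expected=False)
    records, truth = generate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tc_300():
    return TimeControl(300, 0)
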