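import numpy as np
import pytest

from somshunt import simulate


@pytest.fixture(scope="session")
def cruise_casts():
    """Default 6-day 4-hourly cruise simulation (pass-through mode)."""
    return simulate.gen_cruise_casts(simulate.CruiseConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_cruise_casts():
    return simulate.gen_cruise_casts(simulate.CruiseConfig(seed=11, noise_scale=0.0))


@pytest.fixture(scope="session")
def small_climatology():
    """A reduced multi-decadal record (600 casts, 5 contaminated) for tests."""
    cfg = simulate.ClimatologyConfig(seed=7, n_casts=600, n_bottle_pairs=300,
                                     n_contaminated=5)
    return simulate.gen_climatology(cfg)


@pytest.fixture(scope="session")
def count_matrix():
    return simulate.gen_count_matrix(simulate.CountsConfig(seed=3))


@pytest.fixture(scope="session")
def polony_table():
    return simulate.gen_polony_table(simulate.PolonyConfig(seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
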