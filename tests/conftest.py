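import numpy as np
import pytest

from sgem import SGEMParams, TimeGrid, simulate_ensemble


@pytest.fixture(scope="session")
def default_params() -> SGEMParams:
    return SGEMParams(alpha=1e-6, beta=6)


@pytest.fixture(scope="session")
def small_grid() -> TimeGrid:
    return TimeGrid(t_end=4.0, dt=1.0)


@pytest.fixture(scope="session")
def small_ensemble(default_params):
    """A coarse, quick ensemble shared by the summary-statistic tests."""
    return simulate_ensemble(default_params, n=100, t_end=120.0, dt=0.1, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
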