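import numpy as np
import pytest

from methmix import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A reduced cohort quick enough for unit tests."""
    return SimulationConfig(n_samples=300, n_outcomes=40, seed=7)


def make_clustered_data(rng, n=120, m=12, k=3, sigma=1.0, resid_sd=1.0):
    """Simple grouped regression data with known labels for model tests."""
    x = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    beta = rng.normal(size=3)
    labels = np.repeat(np.arange(1, k + 1), n // k)
    alpha = rng.normal(0.0, sigma, size=k)
    y = x @ beta + alpha[labels - 1] + rng.normal(0.0, resid_sd, size=n)
    return y, x, labels, beta, alpha
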