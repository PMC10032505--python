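import numpy as np
import pytest

from cardreg.likelihoods import RegressionDataset, SurvivalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_surv():
    """times (1,2,3), all events, fixed small features."""
    X = np.array([[1.0, 0.5], [-0.5, 1.0], [0.2, -1.0]])
    return SurvivalDataset(X, [1.0, 2.0, 3.0], [1, 1, 1], ("a", "b"))


@pytest.fixture
def random_surv():
    """Factory for random survival datasets with ~20% censoring."""

    def make(seed=0, n=20, p=4):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        times = rng.exponential(1.0, n) + 0.01
        events = (rng.uniform(size=n) > 0.2).astype(int)
        if events.sum() == 0:
            events[0] = 1
        return SurvivalDataset(X, times, events)

    return make


@pytest.fixture
def random_binary():
    def make(seed=0, n=40, p=3, beta=None, intercept=0.0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        beta = np.zeros(p) if beta is None else np.asarray(beta, dtype=float)
        z = intercept + X @ beta
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-z))).astype(int)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        return RegressionDataset(X, y)

    return make
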