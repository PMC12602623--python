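import numpy as np
import pytest

from hetsim import fit_ols


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_fit(rng):
    """A fixed, well-conditioned n=30, p=2 homoskedastic sample."""
    n = 30
    x = rng.standard_normal(n)
    y = 0.5 * x + rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x])
    return fit_ols(X, y)


@pytest.fixture
def two_pred_fit(rng):
    """A fixed n=40, p=3 sample with mildly correlated predictors."""
    n = 40
    z = rng.standard_normal((n, 2))
    z[:, 1] = 0.1 * z[:, 0] + np.sqrt(1 - 0.01) * z[:, 1]
    y = 0.3 * z[:, 1] + rng.standard_normal(n)
    X = np.column_stack([np.ones(n), z])
    return fit_ols(X, y)
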