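import numpy as np
import pytest

from stepglm import make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_glm_data(rng, n, p, family, beta=None, n_signals=3, signal=1.5):
    """Random dataset with a sparse truth; returns (Dataset, beta_full).

    ``beta`` is a length p+1 vector (intercept first); by default the first
    ``n_signals`` predictors carry alternating-sign coefficients of
    magnitude ``signal``.
    """
    X = rng.standard_normal((n, p))
    if beta is None:
        beta = np.zeros(p + 1)
        for j in range(1, min(n_signals, p) + 1):
            beta[j] = signal * (-1) ** j
    eta = beta[0] + X @ beta[1:]
    if family == "gaussian":
        y = eta + rng.standard_normal(n)
    elif family == "binomial":
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    elif family == "poisson":
        y = rng.poisson(np.exp(np.clip(eta, None, 10.0))).astype(float)
    else:
        raise ValueError(family)
    return make_dataset(X, y), beta


@pytest.fixture
def glm_data():
    return make_glm_data
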