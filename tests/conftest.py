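import numpy as np
import pytest
from scipy import integrate, special

from gammadwi import DiffusionThresholds, GammaParams

B_SCHEDULE = (0.0, 500.0, 1000.0, 1500.0, 2000.0)


def laplace_numeric(params, b, upper_mult=80.0):
    """Numeric Laplace transform of the gamma density at b.

    Integrates d^(kappa-1) * g(d) with the singular power handled by the
    quadrature weight (weight='alg'), where g collects the smooth factors
    of the density times exp(-b*d).  Independent of the closed form
    (1+theta*b)**(-kappa).
    """
    k, t = params.kappa, params.theta
    upper = upper_mult * t

    def smooth(d):
        return np.exp(-d / t - b * d - special.gammaln(k) - k * np.log(t))

    val, _ = integrate.quad(
        smooth, 0.0, upper, weight="alg", wvar=(k - 1.0, 0.0), limit=400
    )
    tail = float(special.gammaincc(k, upper / t))
    assert tail < 1e-9, "integration window too short"
    return val


@pytest.fixture
def rng():
    return np.random.default_rng(20240906)


@pytest.fixture
def tumor_params():
    """Benign-tumor-like gamma parameters (kappa ~ 0.06, theta ~ 74.5e-4)."""
    return GammaParams(kappa=0.0623, theta=74.55e-4)


@pytest.fixture
def thresholds():
    return DiffusionThresholds()
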