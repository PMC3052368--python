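import numpy as np
import pytest

import dgrecruit as dg


@pytest.fixture(scope="session")
def default_response_model():
    """Line fitted to the default (30, 5.0%), (45, 4.8%), (150, 2.8%) points."""
    return dg.fit_responsiveness(dg.DEFAULT_RESPONSE_POINTS)


@pytest.fixture(scope="session")
def default_survival():
    """Published parametrization: scale 2218.2 anchored at N(150) = 345."""
    return dg.default_survival_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def brute_force_recruitment(survival, response, t: int) -> float:
    """Independent daily double-sum oracle for the recruitment convolution.

    Plain-python arithmetic on the model parameters; deliberately does not
    call the package's probability or cohort helpers.
    """
    a = response.intercept_at_birth
    r = response.slope_per_day
    mat = response.maturation_age_days
    total = 0.0
    for tau in range(survival.start_age_days, int(t - mat) + 1):
        age = t - tau
        p = a + r * age
        if age < mat or p < 0:
            p = 0.0
        total += survival.scale * tau ** survival.exponent * p
    return total


def closed_form_ols(x, y):
    """Normal-equation OLS slope/intercept, independent of scipy."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    # centered form of the normal equations (numerically stable)
    dx = x - x.mean()
    slope = (dx * (y - y.mean())).sum() / (dx * dx).sum()
    intercept = y.mean() - slope * x.mean()
    return slope, intercept
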