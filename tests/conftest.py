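import warnings

import numpy as np
import pytest

import cvprofiles as cv

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def params():
    """Calibrated default generator parameters (n = 727)."""
    return cv.default_params()


@pytest.fixture(scope="session")
def cohort(params):
    """One complete default cohort, seed 1."""
    return cv.simulate_cohort(params, seed=1)


@pytest.fixture(scope="session")
def cohort_missing(params, cohort):
    return cv.apply_missingness(cohort, params, seed=2)


@pytest.fixture(scope="session")
def risk_matrix(cohort_missing):
    return cv.standardize(cohort_missing)


@pytest.fixture(scope="session")
def lpa_fit(risk_matrix):
    """Unconditional 2-class fit on the default cohort."""
    return cv.fit_lpa(risk_matrix, 2, seed=3)


@pytest.fixture(scope="session")
def toy_two_cluster():
    """Two well-separated clusters on 7 indicators, n = 60."""
    rng = np.random.default_rng(5)
    a = rng.normal(-2.0, 0.5, size=(30, 7))
    b = rng.normal(2.0, 0.5, size=(30, 7))
    X = np.vstack([a, b])
    return cv.RiskMatrix(
        X=X, mask=np.ones_like(X, bool), means=np.zeros(7), sds=np.ones(7)
    )
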