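import numpy as np
import pytest

from ltcond import Cohort, LiabilityModel


@pytest.fixture(scope="session")
def t2d_model():
    """Toy type 2 diabetes model: 0.08*(BMI-26.5)-1.44."""
    return LiabilityModel(["bmi"], [0.08], [26.5], -1.44)


@pytest.fixture(scope="session")
def prostate_model():
    """Prostate cancer worked example: 0.05*(age-50)-2.5."""
    return LiabilityModel(["age"], [0.05], [50.0], -2.5)


@pytest.fixture(scope="session")
def toy_strata():
    """The four (BMI, status) cells of the matched toy design."""
    return [(24.0, 1), (35.0, 1), (24.0, 0), (35.0, 0)]


def make_cohort(status, covariates, names=("bmi",), onset=None):
    status = np.asarray(status)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(status):
        X = X.T
    ids = [f"s{i}" for i in range(len(status))]
    return Cohort(ids, status, names, X, onset_flags=onset)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
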