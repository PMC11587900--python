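import numpy as np
import pandas as pd
import pytest

from obsmed import SurveyDesign, TruthParams, generate_cohort


@pytest.fixture(scope="session")
def cohort_small() -> pd.DataFrame:
    """A 1200-person synthetic cohort with the default study conditions."""
    return generate_cohort(TruthParams(n=1200, seed=42))


@pytest.fixture(scope="session")
def design_small(cohort_small) -> SurveyDesign:
    return SurveyDesign.from_frame(cohort_small)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def simulate_logistic(rng, n, beta, intercept=0.0):
    """iid logistic data with known coefficients, for reduction checks."""
    beta = np.asarray(beta, dtype=float)
    X = rng.normal(size=(n, beta.size))
    eta = intercept + X @ beta
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return X, y
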