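import numpy as np
import pytest

from actistate import CohortConfig, generate_cohort
from actistate.preprocess import preprocess_daily


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient cohort with the default study-like structure."""
    return generate_cohort(CohortConfig(n_patients=40, seed=11))


@pytest.fixture(scope="session")
def small_weekly(small_cohort):
    return preprocess_daily(small_cohort.daily)


@pytest.fixture(scope="session")
def clean_cohort():
    """Fully observed cohort: no missing days, no skipped surveys."""
    return generate_cohort(
        CohortConfig(n_patients=25, seed=5, p_missing_day=0.0, p_missing_survey=0.0)
    )
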