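import logging

import numpy as np
import pytest

import remcm

logging.getLogger("remcm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cohort_and_truth():
    """Default synthetic cohort (20 subjects, 40 regions, 5 visits)."""
    return remcm.make_cohort(seed=11)


@pytest.fixture(scope="session")
def cohort(cohort_and_truth):
    return cohort_and_truth[0]


@pytest.fixture(scope="session")
def zcohort(cohort):
    return remcm.zscore_imaging(cohort)


@pytest.fixture(scope="session")
def full_fits(zcohort):
    return remcm.fit_cohort(zcohort)


@pytest.fixture(scope="session")
def restricted_fits(zcohort):
    return remcm.fit_cohort(zcohort, [])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
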