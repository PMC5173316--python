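import numpy as np
import pytest

from hpbcr.cohort import default_spec, generate_synthetic_cohort


@pytest.fixture(scope="session")
def cohort_spec():
    return default_spec()


@pytest.fixture(scope="session")
def null_spec(cohort_spec):
    return cohort_spec.null()


@pytest.fixture(scope="session")
def study_cohort(cohort_spec):
    """A default-spec cohort at the study size (579 patients)."""
    return generate_synthetic_cohort(cohort_spec, 579, seed=20240579)


@pytest.fixture(scope="session")
def big_cohort(cohort_spec):
    """A large cohort for marginal-calibration checks."""
    return generate_synthetic_cohort(cohort_spec, 5000, seed=20240500)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
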