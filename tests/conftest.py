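import numpy as np
import pytest

from adcascade.cohort import CohortSpec, generate_cohort


def separable_profile() -> dict:
    """Clinical profile with classes so far apart that any learner
    separates them perfectly — used for cascade-contract checks."""
    base = {"age": (70.0, 1.0), "education_years": (16.0, 1.0),
            "sex": 0.5, "married": 0.7, "apoe4": 0.3}
    gaps = {
        "NC": {"cdr": (0.0, 0.05), "faq": (0.0, 0.05), "mmse": (30.0, 0.05)},
        "EMCI": {"cdr": (5.0, 0.05), "faq": (10.0, 0.05), "mmse": (25.0, 0.05)},
        "LMCI": {"cdr": (10.0, 0.05), "faq": (20.0, 0.05), "mmse": (20.0, 0.05)},
        "AD": {"cdr": (20.0, 0.05), "faq": (40.0, 0.05), "mmse": (10.0, 0.05)},
    }
    return {lab: {**base, **gaps[lab]} for lab in gaps}


@pytest.fixture(scope="session")
def separable_cohort():
    """60 subjects (15 per class), perfectly separable on clinical scores."""
    spec = CohortSpec(
        n_per_class=(15, 15, 15, 15), d=6, s=2, seed=11,
        clinical_profile=separable_profile(),
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest ADNI-like cohort for generic pipeline tests."""
    spec = CohortSpec(n_per_class=(40, 30, 30, 25), d=12, s=4, seed=5)
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
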