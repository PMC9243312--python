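import numpy as np
import pytest

from eegauth import synth


@pytest.fixture(scope="session")
def small_cohort() -> synth.CohortSpec:
    return synth.scaled_cohort(4, 20, seed=7)


@pytest.fixture(scope="session")
def profile(small_cohort) -> synth.SubjectProfile:
    return synth.sample_profile(small_cohort, 0)


@pytest.fixture(scope="session")
def noisefree_profile() -> synth.SubjectProfile:
    cohort = synth.scaled_cohort(2, 20, seed=3, noise_level=0.0,
                                 jitter_scale=0.0)
    return synth.sample_profile(cohort, 0)


@pytest.fixture(scope="session")
def small_epochs(profile):
    """A small mixed-class epoch set for one subject."""
    return synth.synthesize_subject(
        profile, {"self": 8, "familiar": 4, "stranger": 4, "blank": 4})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
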