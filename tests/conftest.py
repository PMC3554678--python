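import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from recalib import AttributionModel, GeneratorParams, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_params():
    """A quick 5-subject cohort, still large enough for every fit stage."""
    return GeneratorParams(n_subjects=5, n_pairs=90, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return generate_cohort(small_params)


@pytest.fixture(scope="session")
def study_params():
    """The study conditions: 11 subjects, 180 pairs, perceptual noise 4°."""
    return GeneratorParams(seed=42)


@pytest.fixture(scope="session")
def study_fit(study_params):
    """Full-pipeline fit of one study-sized cohort (shared across tests)."""
    trials, samples = generate_cohort(study_params)
    return AttributionModel(trials, samples).fit()
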