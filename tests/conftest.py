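import numpy as np
import pytest

from pedarch.pipeline import process_foot_meshes
from pedarch.synthetic import (
    SyntheticCohortSpec,
    default_foot_spec,
    default_gait_spec,
    make_cohort,
    make_foot,
    make_pressure_trials,
)


@pytest.fixture(scope="session")
def synthetic_foot():
    """One synthetic foot in a random scanner pose, with ground truth."""
    return make_foot(default_foot_spec(seed=11))


@pytest.fixture(scope="session")
def processed_foot(synthetic_foot):
    """The pipeline's 84-variable vector and foot frame for that foot."""
    return process_foot_meshes(synthetic_foot.meshes)


@pytest.fixture(scope="session")
def clean_trials():
    """Five jitter-free walking trials plus analytic ground truth."""
    spec = default_gait_spec(seed=7)
    spec.jitter_translation_mm = 0.0
    spec.jitter_rotation_deg = 0.0
    spec.amplitude_cv = 0.0
    return make_pressure_trials(spec)


@pytest.fixture(scope="session")
def jittered_trials():
    """Five trials with the default rigid and amplitude jitter."""
    return make_pressure_trials(default_gait_spec(seed=7))


@pytest.fixture(scope="session")
def cohort():
    """A 16-patient cohort (7 N / 8 D / 1 LADA) with the default planted
    angle-load link."""
    return make_cohort(SyntheticCohortSpec(seed=13))


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
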