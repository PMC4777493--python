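import pytest

from osanl.pipeline import extract_cohort_features
from osanl.synthetic import SyntheticSpec, generate_cohort, generate_recording

COHORT_SEED = 1
COHORT_N = 40
COHORT_DURATION = 6 * 3600.0


@pytest.fixture(scope="session")
def cohort():
    """40 simulated subject-nights (6 h at simulation rates)."""
    return generate_cohort(COHORT_N, seed=COHORT_SEED, duration=COHORT_DURATION)


@pytest.fixture(scope="session")
def cohort_table(cohort):
    """Full feature table for the session cohort."""
    return extract_cohort_features(cohort)


@pytest.fixture(scope="session")
def short_recording():
    """A single 6 h recording with moderate event load."""
    spec = SyntheticSpec(duration=COHORT_DURATION, true_ahi=20.0, seed=5)
    rec, events = generate_recording(spec)
    return rec, events, spec
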