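import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcdmorph import extract_features, synth

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: seed used for the shared full-pipeline cohort
COHORT_SEED = 1


@pytest.fixture(scope="session")
def waveform_cohort():
    """A full 33/33 synthetic waveform cohort at default study conditions."""
    spec = synth.CohortSpec()
    exams, truth = synth.generate_cohort(spec, COHORT_SEED)
    return spec, exams, truth


@pytest.fixture(scope="session")
def cohort_features(waveform_cohort):
    """Feature rows extracted from the shared cohort via the full pipeline."""
    _, exams, _ = waveform_cohort
    rows, skips = extract_features(exams)
    return rows, skips


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
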