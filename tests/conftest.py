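import warnings

import numpy as np
import pytest

from nirspeech.montage import default_montage
from nirspeech.simulate import (
    GroundTruth, generate_cohort, generate_events, simulate_participant,
)

# the pipeline emits informational warnings (skipped stages, SCI flags) that
# are part of tested behaviour; keep test output readable
warnings.filterwarnings("ignore", category=UserWarning, module="nirspeech")


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def events_default():
    return generate_events(trials_per_condition=20, seed=5)


@pytest.fixture(scope="session")
def noisy_recording(events_default):
    """One participant under the default (study-condition) generator."""
    return simulate_participant(GroundTruth(seed=3), events=events_default)


@pytest.fixture(scope="session")
def silent_recording():
    """Noise-free participant on an isolated-trial schedule (no response
    overlap), for closed-form recovery checks."""
    events = generate_events(
        trials_per_condition=6, duration_range=(5.6, 5.6),
        gap_range=(35.0, 40.0), seed=5,
    )
    return simulate_participant(GroundTruth(seed=3).silent(), events=events,
                                post_roll=45.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared scaled-down cohort (5 participants, 8 trials/condition)."""
    return generate_cohort(n_participants=5, seed=17, trials_per_condition=8)


def assert_allclose(a, b, **kw):
    np.testing.assert_allclose(a, b, **kw)
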