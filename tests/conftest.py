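import numpy as np
import pytest

from gazebiom.data_model import Blink, Fixation, Recording, Saccade, SceneGeometry
from gazebiom.feature_table import cohort_features
from gazebiom.synthetic import sample_profiles, sample_routes, simulate_cohort


@pytest.fixture(scope="session")
def geometry():
    return SceneGeometry()


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects x 4 routes, full heterogeneity, short recordings."""
    return simulate_cohort(6, 4, 1.0, seed=11, duration=200.0)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return cohort_features(small_cohort, 25.0)


@pytest.fixture(scope="session")
def profile():
    return sample_profiles(1, 1.0, seed=5)[0]


@pytest.fixture(scope="session")
def route():
    return sample_routes(1, seed=5)[0]


def make_recording(fix_times=None, duration=None, subject="S01", route="R1",
                   tracking_ratio=1.0):
    """Hand-built recording: fixations at given (onset, offset, cx, cy)."""
    fix_times = fix_times or []
    fixations = [Fixation(on, off, cx, cy, dispersion=5.0, mean_pupil=3.0)
                 for on, off, cx, cy in fix_times]
    if duration is None:
        duration = max((f.offset for f in fixations), default=0.0)
    return Recording(
        subject_id=subject, route_id=route, geometry=SceneGeometry(),
        fixations=fixations, tracking_ratio=tracking_ratio, duration=duration)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
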