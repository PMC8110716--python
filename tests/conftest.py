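import numpy as np
import pytest

from convo_timing.core_timeline import ActivityTrack, Interval
from convo_timing.synthetic_data import default_profiles


@pytest.fixture(scope="session")
def profiles():
    profs, _ = default_profiles()
    return profs


@pytest.fixture(scope="session")
def cohort_profile():
    _, coh = default_profiles()
    return coh


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_track(rng, speaker="S", trial="describe", max_intervals=12,
                 min_len=0.02, max_len=2.0, min_gap=0.001, max_gap=1.5):
    """Random valid ActivityTrack for property tests."""
    n = int(rng.integers(0, max_intervals + 1))
    t = float(rng.uniform(0, 0.5))
    ivs = []
    for _ in range(n):
        dur = float(rng.uniform(min_len, max_len))
        ivs.append(Interval(t, t + dur))
        t += dur + float(rng.uniform(min_gap, max_gap))
    return ActivityTrack(speaker, trial, ivs, session_end=t + 0.2)
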