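import numpy as np
import pytest

from hrvfatigue.preprocess import NNSeries, Segment
from hrvfatigue.simulate import simulate_cohort


def make_segment(intervals_ms, start_s=0.0, window_s=300.0, **meta) -> Segment:
    """Segment whose onsets are the cumulative beat times of the intervals."""
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    if intervals_ms.size == 0:
        onsets = np.array([])
    else:
        onsets = start_s + np.concatenate(
            [[0.0], np.cumsum(intervals_ms[:-1])]) / 1000.0
    return Segment(nn=NNSeries(intervals_ms, onsets), window_start_s=start_s,
                   window_s=window_s, **meta)


@pytest.fixture(scope="session")
def default_cohort():
    """Default 80-subject synthetic cohort, featurized; shared across tests
    (simulation plus the 24-feature battery takes ~30 s)."""
    table, sessions = simulate_cohort(n_subjects=80, seed=2024)
    return table, sessions


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
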