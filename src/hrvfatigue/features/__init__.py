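"""The 24-feature HRV battery: 10 time-domain, 7 frequency-domain and 7
nonlinear measures per 5-minute NN segment."""

from __future__ import annotations

import pandas as pd

from ..preprocess import Segment
from .time_domain import TIME_FEATURE_NAMES, time_features
from .frequency import FREQ_FEATURE_NAMES, frequency_features
from .nonlinear import NONLINEAR_FEATURE_NAMES, nonlinear_features

#: Canonical feature order used in every feature table.
FEATURE_NAMES = TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES + NONLINEAR_FEATURE_NAMES

__all__ = [
    "FEATURE_NAMES", "TIME_FEATURE_NAMES", "FREQ_FEATURE_NAMES",
    "NONLINEAR_FEATURE_NAMES", "extract_features", "extract_feature_table",
    "time_features", "frequency_features", "nonlinear_features",
]


def extract_features(seg: Segment) -> dict:
    """All 24 HRV features of one segment, in canonical order."""
    out = time_features(seg)
    out.update(frequency_features(seg))
    out.update(nonlinear_features(seg))
    return {k: out[k] for k in FEATURE_NAMES}


def extract_feature_table(segments) -> pd.DataFrame:
    """Feature matrix plus label/grouping metadata for a list of segments."""
    rows = []
    for seg in segments:
        row = extract_features(seg)
        row["subject_id"] = seg.subject_id
        row["session_id"] = seg.session_id
        row["stage"] = seg.stage
        row["window_start_s"] = seg.window_start_s
        row["rpe"] = seg.rpe
        row["class"] = (seg.fatigue_class.value
                        if seg.fatigue_class is not None else None)
        rows.append(row)
    return pd.DataFrame(rows)
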