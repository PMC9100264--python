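"""ECG ingestion, denoising, R-peak detection and NN-interval preparation.

The pipeline front end: read an ECG (or precomputed RR/NN intervals), clean
the waveform, locate R peaks, build an artifact-filtered normal-to-normal
(NN) interval series, cut it into 5-minute analysis segments and attach
Borg-RPE-derived fatigue class labels.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from . import _wavelet

logger = logging.getLogger(__name__)

#: Physiologic band for acceptable NN intervals (ms). Intervals outside are
#: treated as artifacts/ectopy and dropped.
NN_BAND_MS = (300.0, 2000.0)
#: Maximum relative deviation from the running median of the previous
#: accepted intervals before an interval is rejected as an artifact.
NN_MAX_REL_DEV = 0.20
#: Window (number of previously accepted beats) for the running median.
NN_MEDIAN_WINDOW = 5

DEFAULT_WINDOW_S = 300.0
MIN_BEATS_PER_SEGMENT = 100


class FatigueClass(enum.Enum):
    """Three-level fatigue state derived from the Borg 6-20 RPE scale."""

    RESTED = "Rested"
    A_BIT_TIRED = "ABitTired"
    TIRED = "Tired"


@dataclass
class ECGRecord:
    """A single-lead ECG trace with its sampling rate."""

    samples: np.ndarray  # mV
    fs: float  # Hz
    lead: str = "V3"
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("ECG record has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG record contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class RPeakSeries:
    """Detected R-peak sample indices for one record."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64).ravel()
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs


@dataclass
class NNSeries:
    """Artifact-filtered normal-to-normal intervals with onset times.

    ``intervals_ms[i]`` spans from ``onsets_s[i]`` (the earlier beat) to the
    following accepted beat; rejected beats leave gaps in the onset grid.
    """

    intervals_ms: np.ndarray
    onsets_s: np.ndarray
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float).ravel()
        self.onsets_s = np.asarray(self.onsets_s, dtype=float).ravel()
        if self.intervals_ms.size != self.onsets_s.size:
            raise ValueError("intervals and onsets must have equal length")
        if self.onsets_s.size > 1 and np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return int(self.intervals_ms.size)

    def crop(self, t0: float, t1: float) -> "NNSeries":
        """Sub-series with onsets in the half-open window [t0, t1)."""
        m = (self.onsets_s >= t0) & (self.onsets_s < t1)
        return NNSeries(self.intervals_ms[m], self.onsets_s[m],
                        self.subject_id, self.session_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_s": self.onsets_s, "interval_ms": self.intervals_ms}
        )


@dataclass
class StageLabel:
    """Protocol-stage annotation: a time span with its reported RPE."""

    stage: str
    start_s: float
    end_s: float
    rpe: int | None = None


@dataclass
class Segment:
    """One 5-minute NN window, the unit of feature extraction."""

    nn: NNSeries
    window_start_s: float
    window_s: float = DEFAULT_WINDOW_S
    rpe: int | None = None
    fatigue_class: FatigueClass | None = None
    stage: str = ""
    subject_id: str = ""
    session_id: str = ""


def map_rpe_to_class(rpe: int) -> FatigueClass:
    """Map a Borg RPE rating (integer 6-20) to the three fatigue classes.

    6-10 -> Rested, 11-16 -> A bit tired, 17-20 -> Tired.
    """
    if isinstance(rpe, bool) or not float(rpe).is_integer():
        raise ValueError(f"RPE must be an integer, got {rpe!r}")
    rpe = int(rpe)
    if not 6 <= rpe <= 20:
        raise ValueError(f"RPE must lie in [6, 20], got {rpe}")
    if rpe <= 10:
        return FatigueClass.RESTED
    if rpe <= 16:
        return FatigueClass.A_BIT_TIRED
    return FatigueClass.TIRED


def load_ecg(path: str | Path, fs: float | None = None, *,
             format: str = "csv", lead: str = "V3",
             subject_id: str = "", session_id: str = "") -> ECGRecord:
    """Load an ECG record from a plain-text file.

    CSV dialects: one amplitude (mV) per row, or two columns ``time_s,mV``
    (the sampling rate is then inferred from the time column unless given).
    A header row is tolerated. ``fs`` must be supplied for single-column
    files — there is no silent default.
    """
    path = Path(path)
    if format == "wfdb":
        raise NotImplementedError(
            "WFDB input requires the 'wfdb' package, which is not available; "
            "convert the record to CSV (one mV sample per row)"
        )
    if format != "csv":
        raise ValueError(f"unknown ECG format {format!r}")
    if not path.exists():
        raise FileNotFoundError(f"ECG file not found: {path}")

    try:
        df = pd.read_csv(path, header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse ECG CSV {path}: {exc}") from exc
    # Tolerate a single header row of non-numeric labels.
    if df.shape[0] and df.iloc[0].apply(
            lambda v: isinstance(v, str) and not _is_number(v)).any():
        df = df.iloc[1:].reset_index(drop=True)
    try:
        values = df.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"unparseable rows in ECG CSV {path}: {exc}") from exc

    if values.shape[1] == 1:
        if fs is None:
            raise ValueError(
                f"sampling rate required for single-column ECG CSV {path}; "
                "pass fs explicitly"
            )
        samples = values[:, 0]
    elif values.shape[1] == 2:
        t, samples = values[:, 0], values[:, 1]
        if fs is None:
            dt = np.diff(t)
            if dt.size == 0 or np.any(dt <= 0):
                raise ValueError(f"time column of {path} is not increasing")
            fs = 1.0 / float(np.median(dt))
    else:
        raise ValueError(
            f"ECG CSV {path} must have 1 (mV) or 2 (time_s,mV) columns, "
            f"got {values.shape[1]}"
        )
    return ECGRecord(samples, float(fs), lead=lead,
                     subject_id=subject_id, session_id=session_id)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def load_nn(path: str | Path, *, subject_id: str = "",
            session_id: str = "") -> NNSeries:
    """Read an NN-interval CSV with header ``onset_s,interval_ms``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NN file not found: {path}")
    df = pd.read_csv(path)
    missing = {"onset_s", "interval_ms"} - set(df.columns)
    if missing:
        raise ValueError(f"NN CSV {path} lacks columns {sorted(missing)}")
    return NNSeries(df["interval_ms"].to_numpy(float),
                    df["onset_s"].to_numpy(float),
                    subject_id=subject_id, session_id=session_id)


def denoise(ecg: ECGRecord, cutoff_hz: float = 50.0,
            wavelet_levels: int = 9) -> ECGRecord:
    """Clean an ECG trace: zero-phase Butterworth low-pass plus wavelet
    baseline/noise suppression.

    The low-pass (4th order, forward-backward) removes content above
    ``cutoff_hz``. The db8 decomposition then zeroes the deepest
    approximation (baseline wander) and soft-thresholds the two finest
    detail levels with the universal threshold sigma*sqrt(2 ln n), sigma
    estimated from the finest details via the median absolute deviation.
    """
    nyq = ecg.fs / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyq} Hz"
        )
    n = ecg.samples.size
    min_len = 2 ** wavelet_levels
    if n < max(min_len, 30):  # filtfilt padding needs some headroom too
        raise ValueError(
            f"record of {n} samples too short for {wavelet_levels}-level "
            "denoising"
        )
    sos = signal.butter(4, cutoff_hz, btype="low", fs=ecg.fs, output="sos")
    x = signal.sosfiltfilt(sos, ecg.samples)

    # Pad (edge-replicate) to a multiple of 2^levels for the periodized DWT.
    block = 2 ** wavelet_levels
    pad = (-n) % block
    xp = np.concatenate([x, np.full(pad, x[-1])]) if pad else x
    coeffs = _wavelet.wavedec(xp, wavelet_levels)
    approx, details = coeffs[0], coeffs[1:]  # details: level L .. level 1

    baseline_approx = approx.copy()
    approx[:] = 0.0  # level-L approximation carries baseline wander

    finest = details[-1]
    sigma = np.median(np.abs(finest)) / 0.6745 if finest.size else 0.0
    thr = sigma * np.sqrt(2.0 * np.log(max(xp.size, 2)))
    for d in details[-2:]:  # soft-threshold detail levels 1 and 2
        np.copyto(d, np.sign(d) * np.maximum(np.abs(d) - thr, 0.0))

    # A constant record is pure baseline; removing it would zero the signal,
    # so keep the DC level (the policy removes *wander*, not the mean).
    rec = _wavelet.waverec([approx] + details)[:n]
    rec = rec + np.mean(_wavelet.waverec(
        [baseline_approx] + [np.zeros_like(d) for d in details])[:n])
    return ECGRecord(rec, ecg.fs, lead=ecg.lead,
                     subject_id=ecg.subject_id, session_id=ecg.session_id)


def detect_r_peaks(ecg: ECGRecord, refractory_s: float = 0.2) -> RPeakSeries:
    """Locate R peaks with a Pan-Tompkins-style detector.

    Band-pass (5-15 Hz) -> derivative -> squaring -> moving-window
    integration (150 ms) -> peak picking with an adaptive threshold and a
    200 ms refractory period; each candidate is then refined to the local
    maximum of the band-passed waveform, so zero-phase filtering keeps the
    reported index aligned with the true R wave.
    """
    if ecg.fs < 100:
        raise ValueError(f"R-peak detection needs fs >= 100 Hz, got {ecg.fs}")
    if ecg.duration_s < 10:
        raise ValueError(
            f"record of {ecg.duration_s:.1f} s too short for reliable "
            "R-peak detection (need >= 10 s)"
        )
    fs = ecg.fs
    sos = signal.butter(2, [5.0, 15.0], btype="band", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, ecg.samples)
    deriv = np.gradient(bp)
    sq = deriv ** 2
    win = max(int(round(0.150 * fs)), 1)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    # Absolute floor: QRS complexes are O(1 mV); a band-passed amplitude
    # below 10 uV is baseline/numerical noise, not cardiac activity.
    if np.max(np.abs(bp)) < 1e-2:
        return RPeakSeries(np.array([], dtype=np.int64), fs)

    height = 0.08 * np.percentile(integ, 99)
    dist = max(int(round(refractory_s * fs)), 1)
    cand, _ = signal.find_peaks(integ, height=height, distance=dist)
    if cand.size == 0:
        return RPeakSeries(np.array([], dtype=np.int64), fs)

    # Refine each integration peak to the nearby band-passed maximum.
    half = max(int(round(0.10 * fs)), 1)
    refined = []
    for c in cand:
        lo, hi = max(c - half, 0), min(c + half + 1, bp.size)
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = np.unique(refined)
    # Re-impose the refractory period after refinement (keep larger peak).
    keep: list[int] = []
    for idx in refined:
        if keep and idx - keep[-1] < dist:
            if bp[idx] > bp[keep[-1]]:
                keep[-1] = int(idx)
        else:
            keep.append(int(idx))
    return RPeakSeries(np.asarray(keep, dtype=np.int64), fs)


def filter_nn_artifacts(intervals_ms: np.ndarray, onsets_s: np.ndarray,
                        band_ms: tuple[float, float] = NN_BAND_MS,
                        max_rel_dev: float = NN_MAX_REL_DEV,
                        median_window: int = NN_MEDIAN_WINDOW):
    """Drop non-physiologic intervals.

    An interval is rejected if it falls outside ``band_ms`` or deviates more
    than ``max_rel_dev`` from the running median of the previous
    ``median_window`` accepted intervals. Rejected intervals are removed,
    never interpolated.
    """
    keep_i: list[float] = []
    keep_t: list[float] = []
    recent: list[float] = []
    for iv, t in zip(intervals_ms, onsets_s):
        if not band_ms[0] <= iv <= band_ms[1]:
            continue
        if recent:
            med = float(np.median(recent))
            if abs(iv - med) > max_rel_dev * med:
                continue
        keep_i.append(float(iv))
        keep_t.append(float(t))
        recent.append(float(iv))
        if len(recent) > median_window:
            recent.pop(0)
    return np.asarray(keep_i), np.asarray(keep_t)


def to_nn_series(peaks: RPeakSeries, *, subject_id: str = "",
                 session_id: str = "", apply_filter: bool = True) -> NNSeries:
    """Convert detected R peaks into an artifact-filtered NN series.

    Interval i spans peaks i..i+1 in ms; its onset is the earlier peak's
    time in seconds from the start of the record.
    """
    if peaks.indices.size < 2:
        raise ValueError(
            f"need at least 2 R peaks to form intervals, got {peaks.indices.size}"
        )
    intervals = np.diff(peaks.indices) / peaks.fs * 1000.0
    onsets = peaks.indices[:-1] / peaks.fs
    if apply_filter:
        intervals, onsets = filter_nn_artifacts(intervals, onsets)
    if intervals.size == 0:
        raise ValueError("no valid NN intervals after artifact filtering")
    return NNSeries(intervals, onsets, subject_id=subject_id,
                    session_id=session_id)


def segment_nn(nn: NNSeries, window_s: float = DEFAULT_WINDOW_S,
               labels: Sequence[StageLabel] | None = None,
               min_beats: int = MIN_BEATS_PER_SEGMENT) -> list[Segment]:
    """Cut an NN series into non-overlapping fixed-length windows.

    With stage ``labels``, windowing restarts at each stage onset so every
    emitted segment lies entirely inside one stage and inherits that stage's
    RPE (and mapped fatigue class). Windows with fewer than ``min_beats``
    beats are skipped with a warning. Without labels, unlabeled windows are
    cut from the start of the series.
    """
    if len(nn) == 0:
        raise ValueError("cannot segment an empty NN series")
    if labels is None:
        end = float(nn.onsets_s[-1] + nn.intervals_ms[-1] / 1000.0)
        labels = [StageLabel(stage="", start_s=0.0, end_s=end, rpe=None)]

    out: list[Segment] = []
    for lab in labels:
        n_windows = int(np.floor((lab.end_s - lab.start_s) / window_s))
        for k in range(n_windows):
            t0 = lab.start_s + k * window_s
            sub = nn.crop(t0, t0 + window_s)
            if len(sub) < min_beats:
                logger.warning(
                    "segment at %.0f s (stage %r) has %d beats < %d; skipped",
                    t0, lab.stage, len(sub), min_beats)
                continue
            fc = map_rpe_to_class(lab.rpe) if lab.rpe is not None else None
            out.append(Segment(
                nn=sub, window_start_s=t0, window_s=window_s, rpe=lab.rpe,
                fatigue_class=fc, stage=lab.stage,
                subject_id=nn.subject_id, session_id=nn.session_id))
    return out
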