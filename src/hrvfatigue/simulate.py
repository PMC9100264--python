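"""Synthetic treadmill-exercise cohorts for development and testing.

The study-style data are not public, so this module generates a stand-in:
per-subject NN-interval sessions following the modified Bruce protocol
(5-min stages of increasing speed until exhaustion), with a latent fatigue
state that shortens the mean interbeat interval, damps its LF/HF
oscillatory structure and drives the reported Borg RPE. All outputs are
pure functions of their seed and parameters.

Beat-level simulation is the primary path (the HRV features never need a
waveform); :func:`render_ecg` additionally paints QRS-like pulses onto a
sample grid to exercise the ECG front end against planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import extract_feature_table
from .preprocess import (ECGRecord, NNSeries, Segment, StageLabel,
                         map_rpe_to_class, segment_nn)

# -- latent fatigue model constants (per-minute accrual per km/h of speed,
#    scaled by subject fitness; chosen so a median subject is "A bit
#    tired" around Ex-3 and approaches exhaustion during Ex-5/Ex-6) -------
FATIGUE_RATE = 0.007
EX6_MAX_MIN = 15.0

#: Mean NN shortens from baseline toward ~40% of it at high fatigue.
NN_FLOOR_FRAC = 0.40
NN_DECAY = 1.6

#: Oscillatory HRV structure (ms amplitudes at zero fatigue) and its
#: fatigue decay; HF decays faster, so LF/HF rises with fatigue.
LF_FREQ_HZ = 0.10
HF_FREQ_HZ = 0.25
LF_AMP_MS = 30.0
HF_AMP_MS = 20.0
LF_DECAY = 0.8
HF_DECAY = 1.5
JITTER_MS = 12.0
JITTER_FLOOR_MS = 2.0

RPE_NOISE_SD = 0.8


@dataclass
class SubjectProfile:
    """Latent per-subject parameters of the simulator."""

    subject_id: str
    baseline_nn_ms: float = 850.0  # resting mean NN interval
    fitness: float = 0.5  # in [0, 1]; higher = slower fatigue accrual
    hrv_scale: float = 1.0  # baseline variability multiplier
    exhaustion_threshold: float = 1.1  # latent fatigue at which running stops
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 600 <= self.baseline_nn_ms <= 1200:
            raise ValueError("baseline_nn_ms must lie in [600, 1200]")
        if not 0 <= self.fitness <= 1:
            raise ValueError("fitness must lie in [0, 1]")


@dataclass
class Protocol:
    """Ordered treadmill stages: (name, duration_min, speed_kmh, incline_pct).

    The default is the modified Bruce protocol: a standing pre-rest, then
    speed steps 3, 5, 6.4, 7.8, 10.2 km/h of 5 min each, and a final
    11.6 km/h stage run until exhaustion.
    """

    stages: list = field(default_factory=lambda: [
        ("Pre-rest", 5.0, 0.0, 0.0),
        ("Ex-1", 5.0, 3.0, 5.0),
        ("Ex-2", 5.0, 5.0, 5.0),
        ("Ex-3", 5.0, 6.4, 5.0),
        ("Ex-4", 5.0, 7.8, 5.0),
        ("Ex-5", 5.0, 10.2, 5.0),
        ("Ex-6", None, 11.6, 5.0),  # None: until exhaustion
    ])


def draw_profile(subject_id: str, rng: np.random.Generator) -> SubjectProfile:
    """Sample a subject from the cohort's documented distributions."""
    return SubjectProfile(
        subject_id=subject_id,
        baseline_nn_ms=float(np.clip(rng.normal(850.0, 80.0), 600, 1200)),
        fitness=float(rng.beta(2.0, 2.0)),
        hrv_scale=float(np.exp(rng.normal(0.0, 0.25))),
        exhaustion_threshold=float(max(rng.normal(1.1, 0.12), 0.9)),
    )


def _fatigue_rate_per_min(speed_kmh: float, fitness: float) -> float:
    return FATIGUE_RATE * speed_kmh / (0.5 + fitness)


def simulate_session(profile: SubjectProfile,
                     protocol: Protocol | None = None,
                     seed: int | None = None,
                     session_id: str = "s1"):
    """Simulate one treadmill session at beat level.

    Returns ``(nn, stage_labels)``: the NN series and per-stage
    annotations (span + reported RPE). Fatigue accrues in proportion to
    stage speed and inversely to fitness; the session ends early when it
    crosses the subject's exhaustion threshold. RPE is reported at each
    stage end as round(6 + 14*min(f,1) + noise), clipped to [6, 20] and
    non-decreasing within the session.
    """
    protocol = protocol or Protocol()
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    phi_lf, phi_hf = rng.uniform(0, 2 * np.pi, size=2)

    intervals: list[float] = []
    onsets: list[float] = []
    stage_spans: list[tuple[str, float, float, float]] = []  # name, t0, t1, f_end
    t = 0.0  # seconds
    fatigue = 0.0
    exhausted = False
    for name, dur_min, speed, _incline in protocol.stages:
        dur_s = (EX6_MAX_MIN if dur_min is None else dur_min) * 60.0
        stage_start = t
        rate = _fatigue_rate_per_min(speed, profile.fitness) / 60.0  # per s
        while t - stage_start < dur_s:
            f = min(fatigue, 1.2)
            nn_mean = profile.baseline_nn_ms * (
                NN_FLOOR_FRAC + (1 - NN_FLOOR_FRAC) * np.exp(-NN_DECAY * f))
            lf = profile.hrv_scale * LF_AMP_MS * np.exp(-LF_DECAY * f)
            hf = profile.hrv_scale * HF_AMP_MS * np.exp(-HF_DECAY * f)
            jit = profile.hrv_scale * JITTER_MS * np.exp(-f) + JITTER_FLOOR_MS
            nn = (nn_mean
                  + lf * np.sin(2 * np.pi * LF_FREQ_HZ * t + phi_lf)
                  + hf * np.sin(2 * np.pi * HF_FREQ_HZ * t + phi_hf)
                  + rng.normal(0.0, jit))
            nn = float(np.clip(nn, 320.0, 1900.0))
            intervals.append(nn)
            onsets.append(t)
            t += nn / 1000.0
            fatigue += rate * nn / 1000.0
            if speed > 0 and fatigue >= profile.exhaustion_threshold:
                exhausted = True
                break
        stage_spans.append((name, stage_start, t, fatigue))
        if exhausted:
            break

    # RPE is reported at each stage end from the fatigue reached there,
    # with reporting noise; ratings never decrease within a session.
    rpes = [int(np.clip(round(6 + 14 * min(f_end, 1.0)
                              + rng.normal(0.0, RPE_NOISE_SD)), 6, 20))
            for _, _, _, f_end in stage_spans]
    rpes = [int(r) for r in np.maximum.accumulate(rpes)]

    nn_series = NNSeries(np.array(intervals), np.array(onsets),
                         subject_id=profile.subject_id, session_id=session_id)
    labels = [StageLabel(stage=name, start_s=s0, end_s=s1, rpe=rpe)
              for (name, s0, s1, _), rpe in zip(stage_spans, rpes)]
    return nn_series, labels


# -- ECG rendering --------------------------------------------------------

def _qrs_template(fs: float) -> np.ndarray:
    """Symmetric QRS-like pulse: a 1 mV R-wave Gaussian (sigma 10 ms)
    flanked by small Q/S dips. Symmetry keeps the peak centered under
    zero-phase filtering."""
    t = np.arange(-0.1, 0.1 + 1e-9, 1.0 / fs)
    r = np.exp(-0.5 * (t / 0.010) ** 2)
    q = -0.15 * np.exp(-0.5 * ((t + 0.035) / 0.008) ** 2)
    s = -0.15 * np.exp(-0.5 * ((t - 0.035) / 0.008) ** 2)
    return r + q + s


def render_ecg(nn: NNSeries, fs: float = 200.0,
               snr_db: float | None = None,
               seed: int | None = None, pad_s: float = 0.25):
    """Paint QRS pulses at the cumulative beat times of an NN series.

    Returns ``(record, beat_indices)`` where ``beat_indices`` are the
    planted ground-truth R-peak sample positions. ``snr_db=None`` renders
    a noise-free trace; otherwise white Gaussian noise is added at the
    requested signal-to-noise ratio. ``pad_s`` seconds of baseline are
    prepended and appended so the first and last QRS templates are
    complete (and filters have warm-up room); the record length is the
    summed interval duration plus the two pads.
    """
    if len(nn) == 0:
        raise ValueError("cannot render an empty NN series")
    beat_times = np.concatenate(
        [nn.onsets_s, [nn.onsets_s[-1] + nn.intervals_ms[-1] / 1000.0]])
    beat_times = beat_times - beat_times[0] + pad_s
    total_s = float(beat_times[-1]) + pad_s
    n = int(round(total_s * fs)) + 1
    x = np.zeros(n)
    tmpl = _qrs_template(fs)
    half = tmpl.size // 2
    beat_idx = np.round(beat_times * fs).astype(np.int64)
    for b in beat_idx:
        lo = b - half
        hi = lo + tmpl.size
        tlo, thi = max(0, -lo), tmpl.size - max(0, hi - n)
        x[max(lo, 0):min(hi, n)] += tmpl[tlo:thi]
    if snr_db is not None and np.isfinite(snr_db):
        rng = np.random.default_rng(seed)
        p_sig = float(np.mean(x ** 2))
        x = x + rng.normal(0.0, np.sqrt(p_sig / 10 ** (snr_db / 10.0)), n)
    rec = ECGRecord(x, fs, subject_id=nn.subject_id, session_id=nn.session_id)
    return rec, beat_idx


# -- cohort-level generation ----------------------------------------------

def simulate_cohort(n_subjects: int = 80, max_sessions: int = 3,
                    seed: int | None = None, protocol: Protocol | None = None,
                    min_beats: int = 100):
    """Simulate a cohort, segment every session and extract features.

    Each subject completes between 1 and ``max_sessions`` sessions. Returns
    ``(table, sessions)``: the feature table (24 features + subject_id,
    session_id, stage, rpe, class columns) and the raw
    ``(nn, stage_labels)`` pairs keyed by (subject, session).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    sessions = {}
    for i in range(n_subjects):
        sid = f"S{i + 1:03d}"
        profile = draw_profile(sid, rng)
        n_sessions = int(rng.integers(1, max_sessions + 1))
        for j in range(n_sessions):
            ses = f"{sid}-r{j + 1}"
            nn, labels = simulate_session(
                profile, protocol=protocol,
                seed=int(rng.integers(0, 2**31 - 1)), session_id=ses)
            sessions[(sid, ses)] = (nn, labels)
            segments.extend(segment_nn(nn, labels=labels, min_beats=min_beats))
    table = extract_feature_table(segments)
    return table, sessions


def planted_feature_table(n: int = 1000, k_informative: int = 3,
                          k_duplicated: int = 2, k_noise: int = 5,
                          effect_size: float = 3.0,
                          seed: int | None = None):
    """Abstract planted-signal table for selector tests.

    Three balanced classes. Informative columns shift their class mean by
    ``effect_size`` standard deviations per class step; each duplicated
    column copies an informative one plus jitter of 0.2x its sd (giving
    |r| > 0.95 by construction: r = 1/sqrt(1+0.04) ~ 0.98); noise columns
    are i.i.d. standard normal. Returns ``(X, y)`` with X a DataFrame whose
    columns are named inf*/dup*/noise*.
    """
    if n < 50:
        raise ValueError("n must be >= 50")
    if k_duplicated > k_informative:
        raise ValueError("cannot duplicate more columns than exist")
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 3
    y = rng.permutation(y)
    cols = {}
    for i in range(k_informative):
        cols[f"inf{i}"] = y * effect_size + rng.normal(0.0, 1.0, n)
    for i in range(k_duplicated):
        parent = cols[f"inf{i}"]
        cols[f"dup{i}"] = parent + rng.normal(0.0, 0.2 * parent.std(), n)
    for i in range(k_noise):
        cols[f"noise{i}"] = rng.normal(0.0, 1.0, n)
    return pd.DataFrame(cols), y
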