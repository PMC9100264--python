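"""Nonlinear HRV features: sample entropy, Poincaré descriptors and DFA.

Undefined values (zero-variance input, no template matches, zero
fluctuation) are reported as NaN and imputed later, at model-fitting time,
from training folds only.
"""

from __future__ import annotations

import math

import numpy as np

from ..preprocess import Segment

NONLINEAR_FEATURE_NAMES = ["sampen", "SD1", "SD2", "SD1_SD2",
                           "alpha", "alpha1", "alpha2"]

#: DFA box-size layout (beats): log-spaced over 4-64, split at 16 beats
#: into the short-range (alpha1) and long-range (alpha2) scaling regions.
DFA_BOX_MIN = 4
DFA_BOX_MAX = 64
DFA_BOX_SPLIT = 16
DFA_N_BOXES = 12


def sample_entropy(x: np.ndarray, m: int = 2,
                   r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) with A the number of (m+1)-template pairs
    and B the number of m-template pairs within Chebyshev tolerance r,
    self-matches excluded.

    ``r`` defaults to 0.2 x the population standard deviation of ``x``.
    Returns NaN for zero-variance input or when either count is zero.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"series of length {n} too short for m={m}")
    sd = float(np.std(x))
    if r is None:
        r = 0.2 * sd
    if sd == 0 or r <= 0:
        return math.nan

    def count_pairs(mm: int) -> int:
        # Chebyshev distance between all template pairs, vectorized per
        # lag. Both template lengths use the same n-m start positions so
        # every m-template has an (m+1)-point extension.
        n_t = n - m
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_t]
        total = 0
        for lag in range(1, n_t):
            d = np.abs(templ[:-lag] - templ[lag:]).max(axis=1)
            total += int(np.count_nonzero(d <= r))
        return total

    b = count_pairs(m)
    a = count_pairs(m + 1)
    if a == 0 or b == 0:
        return math.nan
    return float(-np.log(a / b))


def poincare(x: np.ndarray) -> dict:
    """Poincaré plot descriptors from successive interval pairs.

    SD1 = population std of (x_{i+1}-x_i)/sqrt(2) — dispersion
    perpendicular to the identity line; SD2 = population std of
    (x_i+x_{i+1})/sqrt(2) — dispersion along it. The ratio is NaN when
    SD2 = 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 intervals for Poincaré analysis, got {x.size}")
    a, b = x[:-1], x[1:]
    sd1 = float(np.std((b - a) / np.sqrt(2.0)))
    sd2 = float(np.std((b + a) / np.sqrt(2.0)))
    # sub-nanosecond dispersion is numerical noise, not physiology
    ratio = sd1 / sd2 if sd2 > 1e-9 else math.nan
    return {"SD1": sd1, "SD2": sd2, "SD1_SD2": ratio}


def _dfa_fluctuation(profile: np.ndarray, box: int) -> float:
    """RMS fluctuation after per-box linear detrending (non-overlapping
    boxes, remainder truncated)."""
    n_boxes = profile.size // box
    if n_boxes == 0:
        return math.nan
    seg = profile[: n_boxes * box].reshape(n_boxes, box)
    t = np.arange(box, dtype=float)
    # Least-squares line per box via closed-form normal equations.
    tm = t.mean()
    tc = t - tm
    denom = float(np.sum(tc ** 2))
    ym = seg.mean(axis=1, keepdims=True)
    slope = (seg @ tc)[:, None] / denom
    resid = seg - ym - slope * tc
    return float(np.sqrt(np.mean(resid ** 2)))


def dfa(x: np.ndarray, box_min: int = DFA_BOX_MIN, box_max: int = DFA_BOX_MAX,
        box_split: int = DFA_BOX_SPLIT, n_boxes: int = DFA_N_BOXES) -> dict:
    """Detrended fluctuation analysis scaling exponents.

    The mean-removed series is integrated; for each box size n the RMS
    fluctuation F(n) about a per-box linear fit is computed; alpha is the
    log-log slope over all box sizes, alpha1 over [box_min, box_split],
    alpha2 over [box_split, box_max]. All three are NaN if any F(n) is 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 100:
        raise ValueError(f"need >= 100 intervals for DFA, got {x.size}")
    sizes = np.unique(np.round(np.geomspace(box_min, min(box_max, x.size // 2),
                                            n_boxes)).astype(int))
    profile = np.cumsum(x - np.mean(x))
    fluct = np.array([_dfa_fluctuation(profile, s) for s in sizes])
    if np.any(~np.isfinite(fluct)) or np.any(fluct <= 0):
        return {"alpha": math.nan, "alpha1": math.nan, "alpha2": math.nan}

    logn, logf = np.log(sizes), np.log(fluct)

    def slope(mask: np.ndarray) -> float:
        if mask.sum() < 2:
            return math.nan
        return float(np.polyfit(logn[mask], logf[mask], 1)[0])

    return {
        "alpha": slope(np.ones_like(sizes, dtype=bool)),
        "alpha1": slope(sizes <= box_split),
        "alpha2": slope(sizes >= box_split),
    }


def nonlinear_features(seg: Segment, m: int = 2,
                       r_factor: float = 0.2) -> dict:
    x = seg.nn.intervals_ms
    sd = float(np.std(x))
    out = {"sampen": sample_entropy(x, m=m, r=r_factor * sd if sd > 0 else None)}
    out.update(poincare(x))
    out.update(dfa(x))
    return {k: out[k] for k in NONLINEAR_FEATURE_NAMES}
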