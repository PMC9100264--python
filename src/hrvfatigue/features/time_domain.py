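"""Time-domain HRV features: 8 statistical and 2 geometric measures.

All features are computed on one 5-minute NN segment. Statistical measures
follow the conventional definitions (SDNN with the n-1 denominator); the
geometric pair (HRVTi, TINN) is derived from the NN histogram with 1/128 s
bins anchored at 0 ms.
"""

from __future__ import annotations

import math

import numpy as np

from ..preprocess import Segment

#: Histogram bin width for the geometric features: 1/128 s in ms.
GEOMETRIC_BIN_MS = 1000.0 / 128.0

TIME_FEATURE_NAMES = [
    "meanNN", "meanHR", "SDNN", "RMSSD", "NN50", "pNN50",
    "SDANN", "SDNNi", "HRVTi", "TINN",
]


def statistical_time_features(seg: Segment, chunk_s: float = 60.0) -> dict:
    """The eight statistical time-domain features.

    SDANN/SDNNi segment the window into non-overlapping ``chunk_s`` chunks
    by onset time; chunks with fewer than 2 beats are excluded from SDNNi,
    and both are NaN when fewer than 2 usable chunks exist.
    """
    x = seg.nn.intervals_ms
    t = seg.nn.onsets_s
    n = x.size
    if n < 2:
        raise ValueError(f"need >= 2 NN intervals, got {n}")

    diffs = np.diff(x)
    nn50 = int(np.sum(np.abs(diffs) > 50.0))  # strictly greater than 50 ms
    feats = {
        "meanNN": float(np.mean(x)),
        "meanHR": float(np.mean(60000.0 / x)),
        "SDNN": float(np.std(x, ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(diffs ** 2))),
        "NN50": nn50,
        "pNN50": nn50 / diffs.size * 100.0,
    }

    rel = t - seg.window_start_s
    chunk_ids = np.floor(rel / chunk_s).astype(int)
    means, stds = [], []
    for cid in np.unique(chunk_ids):
        vals = x[chunk_ids == cid]
        if vals.size >= 1:
            means.append(np.mean(vals))
        if vals.size >= 2:
            stds.append(np.std(vals, ddof=1))
    feats["SDANN"] = float(np.std(means, ddof=1)) if len(means) >= 2 else math.nan
    feats["SDNNi"] = float(np.mean(stds)) if len(stds) >= 2 else math.nan
    return feats


def _nn_histogram(x: np.ndarray, bin_ms: float):
    """Half-open [lo, hi) bins of width ``bin_ms`` anchored at 0 ms."""
    idx = np.floor(x / bin_ms).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    centers = (np.arange(lo, hi + 1) + 0.5) * bin_ms
    return counts.astype(float), centers


def _triangle(centers: np.ndarray, m: float, apex_x: float, apex_y: float,
              nright: float) -> np.ndarray:
    y = np.zeros_like(centers)
    left = (centers >= m) & (centers <= apex_x)
    right = (centers > apex_x) & (centers <= nright)
    if apex_x > m:
        y[left] = apex_y * (centers[left] - m) / (apex_x - m)
    else:
        y[left] = apex_y
    if nright > apex_x:
        y[right] = apex_y * (nright - centers[right]) / (nright - apex_x)
    return y


def geometric_features(seg: Segment, bin_s: float = 1.0 / 128.0) -> dict:
    """HRV triangular index and TINN from the NN histogram.

    HRVTi is the total beat count divided by the modal bin count. TINN is
    the baseline width N - M of the triangle, apex fixed at the modal bin,
    that minimizes the squared difference to the histogram; M and N are
    searched exhaustively over bin centers left/right of the mode. A
    single-occupied-bin histogram degenerates to TINN = 0.
    """
    x = seg.nn.intervals_ms
    if x.size == 0:
        raise ValueError("empty segment")
    bin_ms = bin_s * 1000.0
    counts, centers = _nn_histogram(x, bin_ms)
    mode_i = int(np.argmax(counts))
    hrvti = float(x.size / counts[mode_i])

    occupied = np.nonzero(counts)[0]
    if occupied.size == 1:
        return {"HRVTi": hrvti, "TINN": 0.0}

    apex_x, apex_y = centers[mode_i], counts[mode_i]
    # Candidate baseline endpoints: bin centers at/left of the mode and
    # one bin beyond each flank so a triangle can enclose the support.
    left_cands = np.concatenate(([centers[0] - bin_ms], centers[: mode_i + 1]))
    right_cands = np.concatenate((centers[mode_i:], [centers[-1] + bin_ms]))
    best = (np.inf, 0.0)
    for m in left_cands:
        for nr in right_cands:
            if nr < apex_x or m > apex_x:
                continue
            sse = float(np.sum((counts - _triangle(centers, m, apex_x, apex_y, nr)) ** 2))
            if sse < best[0] - 1e-12:
                best = (sse, float(nr - m))
    return {"HRVTi": hrvti, "TINN": best[1]}


def time_features(seg: Segment, chunk_s: float = 60.0,
                  bin_s: float = 1.0 / 128.0) -> dict:
    out = statistical_time_features(seg, chunk_s=chunk_s)
    out.update(geometric_features(seg, bin_s=bin_s))
    return {k: out[k] for k in TIME_FEATURE_NAMES}
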