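"""Frequency-domain HRV features from a Lomb-Scargle spectrum.

The NN tachogram (interval value vs. interval onset) is irregularly
sampled by construction, so the spectrum is estimated with the
Lomb-Scargle periodogram, which needs no resampling. Band powers are
trapezoidal integrals over the standard VLF/LF/HF bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from ..preprocess import Segment

#: Band edges in Hz, half-open [lo, hi): 0.04 belongs to LF, 0.15 to HF.
VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)

#: Default evaluation grid: uniform 0.0033-0.4 Hz, 1 mHz step (397 points).
DEFAULT_FREQS = np.arange(0.0033, 0.4 + 1e-12, 0.001)

FREQ_FEATURE_NAMES = ["aVLF", "aLF", "aHF", "LF_HF",
                      "peakVLF", "peakLF", "peakHF"]

MIN_BEATS_FOR_PSD = 100


@dataclass
class PowerSpectrum:
    freqs: np.ndarray  # Hz
    power: np.ndarray  # ms^2/Hz


def lomb_psd(seg: Segment, freqs: np.ndarray | None = None,
             min_beats: int = MIN_BEATS_FOR_PSD) -> PowerSpectrum:
    """Lomb-Scargle power spectral density of one NN segment.

    The mean is removed before the transform. The raw periodogram P(omega)
    is scaled by 2*T/N (T the span of the onsets, N the beat count) so that
    its integral over the computed grid approximates the variance of the
    mean-removed series in ms^2 — the even-sampling limit of the one-sided
    PSD convention.
    """
    t = seg.nn.onsets_s
    x = seg.nn.intervals_ms
    if x.size < min_beats:
        raise ValueError(
            f"need >= {min_beats} beats for spectral analysis, got {x.size}")
    if freqs is None:
        freqs = DEFAULT_FREQS
    xc = x - np.mean(x)
    span = float(t[-1] - t[0])
    if span <= 0 or np.ptp(xc) == 0:
        return PowerSpectrum(np.asarray(freqs), np.zeros(len(freqs)))
    raw = lombscargle(t, xc, 2.0 * np.pi * np.asarray(freqs))
    power = raw * 2.0 * span / x.size
    return PowerSpectrum(np.asarray(freqs, dtype=float), power)


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0] - 1e-12) & (freqs < band[1] - 1e-12)


def band_features(psd: PowerSpectrum) -> dict:
    """Absolute band powers, LF/HF ratio and per-band peak frequencies.

    A zero HF power leaves LF/HF as NaN rather than infinity; a band with
    identically zero power reports NaN for its peak frequency.
    """
    f, p = psd.freqs, psd.power
    if f[0] > VLF_BAND[0] + 1e-9 or f[-1] < HF_BAND[1] - 0.001 - 1e-9:
        raise ValueError("spectrum must cover 0.0033-0.4 Hz")
    out: dict[str, float] = {}
    for name, band in (("VLF", VLF_BAND), ("LF", LF_BAND), ("HF", HF_BAND)):
        m = _band_mask(f, band)
        out[f"a{name}"] = float(np.trapezoid(p[m], f[m])) if m.sum() > 1 else 0.0
        if np.any(p[m] > 0):
            out[f"peak{name}"] = float(f[m][np.argmax(p[m])])
        else:
            out[f"peak{name}"] = math.nan
    out["LF_HF"] = out["aLF"] / out["aHF"] if out["aHF"] > 0 else math.nan
    return out


def frequency_features(seg: Segment, freqs: np.ndarray | None = None) -> dict:
    out = band_features(lomb_psd(seg, freqs=freqs))
    return {k: out[k] for k in FREQ_FEATURE_NAMES}
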