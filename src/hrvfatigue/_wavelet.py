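"""Minimal periodized orthogonal wavelet transform (Daubechies-8).

Only what the ECG denoiser needs: a multilevel analysis/synthesis pair with
the 16-tap db8 filter. The transform is the orthogonal matrix whose rows are
the even shifts of the scaling/wavelet filters on a periodic signal, so
synthesis is the exact transpose and reconstruction is perfect (up to float
round-off) for any even-length input at every level.
"""

from __future__ import annotations

import numpy as np

# Standard db8 scaling (low-pass) decomposition coefficients, 16 taps.
DB8_LO = np.array(
    [
        -0.00011747678400228192,
        0.0006754494059985568,
        -0.0003917403729959771,
        -0.00487035299301066,
        0.008746094047015655,
        0.013981027917015516,
        -0.04408825393106472,
        -0.01736930100202211,
        0.128747426620186,
        0.00047248457399797254,
        -0.2840155429624281,
        -0.015829105256023893,
        0.5853546836548691,
        0.6756307362980128,
        0.3128715909144659,
        0.05441584224308161,
    ]
)
# Quadrature-mirror high-pass: g[k] = (-1)^k h[L-1-k]
DB8_HI = np.array([(-1) ** k * DB8_LO[15 - k] for k in range(16)])


def _analysis_indices(n: int, taps: int) -> np.ndarray:
    return (2 * np.arange(n // 2)[:, None] + np.arange(taps)[None, :]) % n


def dwt_periodized(x: np.ndarray, lo: np.ndarray = DB8_LO, hi: np.ndarray = DB8_HI):
    """One analysis step on a periodic signal of even length.

    Returns (approximation, detail), each of length len(x)//2.
    """
    x = np.asarray(x, dtype=float)
    if x.size % 2:
        raise ValueError("periodized DWT requires even length")
    idx = _analysis_indices(x.size, lo.size)
    win = x[idx]
    return win @ lo, win @ hi


def idwt_periodized(approx: np.ndarray, detail: np.ndarray,
                    lo: np.ndarray = DB8_LO, hi: np.ndarray = DB8_HI) -> np.ndarray:
    """Transpose of :func:`dwt_periodized` (exact inverse for orthogonal taps)."""
    n = 2 * approx.size
    idx = _analysis_indices(n, lo.size)
    out = np.zeros(n)
    contrib = approx[:, None] * lo[None, :] + detail[:, None] * hi[None, :]
    np.add.at(out, idx, contrib)
    return out


def wavedec(x: np.ndarray, levels: int):
    """Multilevel analysis; returns [a_L, d_L, d_{L-1}, ..., d_1]."""
    coeffs = []
    a = np.asarray(x, dtype=float)
    for _ in range(levels):
        a, d = dwt_periodized(a)
        coeffs.append(d)
    coeffs.append(a)
    return coeffs[::-1]


def waverec(coeffs) -> np.ndarray:
    a = coeffs[0]
    for d in coeffs[1:]:
        a = idwt_periodized(a, d)
    return a
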