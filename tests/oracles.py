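"""Independent brute-force oracles for cross-checking package computations.

Each oracle re-derives a quantity by a different route from the
implementation it checks: explicit-loop DFT band integration for the
biofeedback score, exhaustive pair enumeration for the cross-pair tau,
inverse-erf quantiles for signal detection, and dummy-variable regression
residuals for repeated-measures correlation.
"""

import numpy as np
from scipy.special import erfinv


def dft_band_score(segment, fs, band_lo, band_hi, nfft):
    """Biofeedback score by naive DFT: mean removal, Hann taper, zero-pad,
    one-sided band-power ratio with explicit exponential sums."""
    y = np.asarray(segment, dtype=float)
    n = y.size
    y = y - y.mean()
    taper = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))  # periodic Hann
    yw = np.zeros(nfft)
    yw[:n] = y * taper
    k = np.arange(nfft // 2 + 1)
    # explicit DFT matrix (slow, independent of any FFT code path)
    expo = np.exp(-2j * np.pi * np.outer(k, np.arange(nfft)) / nfft)
    X = expo @ yw
    power = np.abs(X) ** 2
    power[1:-1] *= 2.0  # one-sided doubling, DC and Nyquist excluded
    freq = k * fs / nfft
    positive = freq > 0
    in_band = (freq >= band_lo) & (freq <= band_hi) & positive
    total = power[positive].sum()
    if total <= 0:
        return 0.0
    return float(power[in_band].sum() / total)


def cross_pair_tau(x, y):
    """Exhaustive O(n*m) concordant/discordant enumeration."""
    c = d = 0
    for xi in x:
        for yj in y:
            if yj > xi:
                c += 1
            elif yj < xi:
                d += 1
    return (c - d) / (len(x) * len(y)), c, d


def sdt_quantile_oracle(hits, misses, fas, crs):
    """d' and criterion via inverse error function (not norm.ppf)."""

    def z(p):
        return np.sqrt(2.0) * erfinv(2.0 * p - 1.0)

    h = (hits + 0.5) / (hits + misses + 1)
    f = (fas + 0.5) / (fas + crs + 1)
    return z(h) - z(f), -(z(h) + z(f)) / 2.0


def rmcorr_regression_oracle(x, y, subjects):
    """rmcorr via least-squares residuals on subject indicator dummies."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    dummies = (subjects[:, None] == uniq[None, :]).astype(float)
    beta_x, *_ = np.linalg.lstsq(dummies, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(dummies, y, rcond=None)
    rx = x - dummies @ beta_x
    ry = y - dummies @ beta_y
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
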