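"""Sliding-window breathing-biofeedback score and baseline summary.

The score rewards slow, deep diaphragmatic breathing: every 2 s the last
30 s of the belt signal are analyzed by spectral density estimation, and the
score is the spectral power (area under the curve) inside the 6-10
breaths/min band (0.1-0.1667 Hz) relative to the total power.  Defining it
as in-band/total — the bounded monotone transform r/(1+r) of the raw
in-band/out-of-band ratio r — keeps the published [0, 1] range while
preserving the ordering of the raw ratio.  Because power is an area, the
score is sensitive to breathing depth whenever a fixed-amplitude noise floor
is present, and to pace through band membership.

Numerical pipeline: linear resampling to a uniform 10 Hz grid, mean removal,
Hann taper, zero-padding to a <= 0.01 Hz frequency grid (a raw 30 s window
resolves only 0.033 Hz — too coarse against a 0.067 Hz-wide band), one-sided
periodogram, rectangular band integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .session_model import BiofeedbackStream, BreathingTrace

__all__ = [
    "ScoreParams",
    "SpectralEstimate",
    "resample_uniform",
    "estimate_breathing_spectrum",
    "biofeedback_value",
    "score_stream",
    "baseline_summary",
    "baseline_span_seconds",
    "BASELINE_REF_SAMPLES",
]

#: shortest baseline recording used as the cohort length reference:
#: 29 score samples at the 0.5 Hz logging rate span (29 - 1) * 2 = 56 s.
BASELINE_REF_SAMPLES = 29


@dataclass(frozen=True)
class ScoreParams:
    """Parameters of the biofeedback computation.

    ``band_lo``/``band_hi`` bound the rewarded 6-10 breaths/min pace band;
    ``target_bpm`` (8) is the rewarded pace, recorded for documentation only
    — the score itself depends on the band, not the target.
    """

    window: float = 30.0          # s of breathing data per analysis segment
    hop: float = 2.0              # s between score updates (0.5 Hz)
    band_lo: float = 6.0 / 60.0   # Hz (6 breaths/min)
    band_hi: float = 10.0 / 60.0  # Hz (10 breaths/min)
    target_bpm: float = 8.0
    resample_hz: float = 10.0     # uniform analysis rate; >> 2 * band_hi
    grid_hz: float = 0.01         # max frequency-grid spacing after padding
    power_floor: float = 1e-10    # relative variance below which score := 0

    def __post_init__(self) -> None:
        if not 0 < self.band_lo < self.band_hi < self.resample_hz / 2:
            raise ValueError("require 0 < band_lo < band_hi < Nyquist")
        if self.hop > self.window:
            raise ValueError("hop must not exceed window")

    @property
    def nperseg(self) -> int:
        return int(round(self.window * self.resample_hz))

    @property
    def nfft(self) -> int:
        """Zero-padded FFT length giving a grid no coarser than ``grid_hz``."""
        n = int(np.ceil(self.resample_hz / self.grid_hz))
        return int(2 ** np.ceil(np.log2(max(n, self.nperseg))))


@dataclass
class SpectralEstimate:
    """One-sided power spectral density on a positive-frequency grid."""

    freq: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if self.freq.size and (self.freq[0] <= 0 or np.any(np.diff(self.freq) <= 0)):
            raise ValueError("freq must be increasing and start above 0")


def resample_uniform(trace: BreathingTrace, fs: float) -> np.ndarray:
    """Linearly resample a trace onto a uniform ``fs`` grid starting at t[0]."""
    n = int(np.floor(trace.duration * fs)) + 1
    tu = trace.t[0] + np.arange(n) / fs
    return np.interp(tu, trace.t, trace.y)


def estimate_breathing_spectrum(
    segment: np.ndarray, params: ScoreParams | None = None
) -> SpectralEstimate:
    """Estimate the PSD of one uniform 30 s breathing segment.

    Mean-removed, Hann-tapered, zero-padded one-sided periodogram; with
    density scaling the integral of the returned power recovers the segment
    variance to within a few percent (taper-corrected).
    """
    params = params or ScoreParams()
    y = np.asarray(segment, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("segment contains non-finite samples")
    if abs(y.size - params.nperseg) > 1:
        raise ValueError(
            f"segment has {y.size} samples; expected {params.nperseg} "
            f"({params.window} s at {params.resample_hz} Hz)"
        )
    freq, pxx = sps.periodogram(
        y,
        fs=params.resample_hz,
        window="hann",
        nfft=params.nfft,
        detrend="constant",
        scaling="density",
    )
    return SpectralEstimate(freq[1:], pxx[1:])  # drop DC


def biofeedback_value(
    spectrum: SpectralEstimate,
    params: ScoreParams | None = None,
    *,
    signal_scale: float = 1.0,
) -> float:
    """In-band area / total area, in [0, 1].

    ``signal_scale`` is the mean square of the raw segment, used only for the
    degenerate-input floor: an (essentially) flat segment — total variance
    below ``power_floor`` relative to the signal scale — scores 0 rather
    than an arbitrary ratio of numerical noise.
    """
    params = params or ScoreParams()
    total = float(np.sum(spectrum.power))
    if total <= params.power_floor * max(1.0, signal_scale):
        return 0.0
    in_band = (spectrum.freq >= params.band_lo) & (spectrum.freq <= params.band_hi)
    score = float(np.sum(spectrum.power[in_band]) / total)
    return float(np.clip(score, 0.0, 1.0))


def _window_matrix(y: np.ndarray, nperseg: int, step: int) -> np.ndarray:
    n_windows = (y.size - nperseg) // step + 1
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_windows)[:, None]
    return y[idx]


def score_stream(trace: BreathingTrace, params: ScoreParams | None = None) -> BiofeedbackStream:
    """Score a whole breathing trace with the sliding 30 s / 2 s hop window.

    The first score is emitted once one full window of data exists, i.e. at
    ``t = t0 + window``, then every ``hop`` seconds.  A trace shorter than
    one window yields an empty stream with a warning (no warm-up scores are
    fabricated).
    """
    params = params or ScoreParams()
    if trace.duration < params.window:
        warnings.warn("trace shorter than one analysis window; empty score stream")
        return BiofeedbackStream(np.empty(0), np.empty(0))
    y = resample_uniform(trace, params.resample_hz)
    step = int(round(params.hop * params.resample_hz))
    nperseg = params.nperseg
    windows = _window_matrix(y, nperseg, step)
    centered = windows - windows.mean(axis=1, keepdims=True)
    taper = sps.get_window("hann", nperseg)
    spec = np.abs(np.fft.rfft(centered * taper, n=params.nfft, axis=1)) ** 2
    # density scaling constant cancels in the ratio; keep it for the floor check
    spec *= 2.0 / (params.resample_hz * np.sum(taper**2))
    freq = np.fft.rfftfreq(params.nfft, 1.0 / params.resample_hz)
    in_band = (freq >= params.band_lo) & (freq <= params.band_hi)
    positive = freq > 0
    total = spec[:, positive].sum(axis=1)
    band = spec[:, in_band & positive].sum(axis=1)
    scale = np.maximum(1.0, (windows**2).mean(axis=1))
    scores = np.where(total > params.power_floor * scale, band / np.maximum(total, 1e-300), 0.0)
    scores = np.clip(scores, 0.0, 1.0)
    t = trace.t[0] + params.window + params.hop * np.arange(scores.size)
    return BiofeedbackStream(t, scores)


def baseline_span_seconds(n_samples: int = BASELINE_REF_SAMPLES, hz: float = 0.5) -> float:
    """Span covered by ``n_samples`` scores at the logging rate (interval count)."""
    return (n_samples - 1) / hz


def baseline_summary(stream: BiofeedbackStream, n_ref: int = BASELINE_REF_SAMPLES) -> float:
    """Mean biofeedback score of the last ``n_ref`` baseline samples.

    Baselines vary in length, so the shortest recording in the cohort
    (29 samples = 56 s at 0.5 Hz) is the length reference: longer baselines
    contribute only their last 29 samples.  Shorter streams are averaged
    whole, with a warning.
    """
    n = len(stream)
    if n == 0:
        raise ValueError("empty biofeedback stream")
    if n < n_ref:
        warnings.warn(f"baseline has only {n} samples (< {n_ref} reference)")
    return float(np.mean(stream.score[-n_ref:]))
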