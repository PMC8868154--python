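"""R-R cleaning, tachogram construction, LF/HF band powers, and coherence.

Heart-rate variability is quantified spectrally: the irregular R-R interval
series is interpolated onto a uniform 4 Hz tachogram (cubic spline, standard
HRV practice), and Welch power is integrated over the low-frequency
(0.04-0.15 Hz) and high-frequency (0.15-0.4 Hz) bands.  Slow paced breathing
(6-10 breaths/min = 0.1-0.167 Hz) drives respiratory sinus arrhythmia into
and around the LF band, so the similarity between breathing and the
tachogram is summarized as the mean magnitude-squared coherence over the LF
band — a [0, 1] index of breathing-driven LF HRV.

Welch settings (60 s Hann segments, 50% overlap) give >= 4 averaged
segments in a 15-min session at a 0.017 Hz resolution, finer than the LF
bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .session_model import BreathingTrace, RRSeries, SessionRecord

__all__ = [
    "HRVParams",
    "HRVMetrics",
    "CleanResult",
    "Tachogram",
    "clean_rr",
    "rr_to_tachogram",
    "hrv_band_powers",
    "breathing_lf_coherence",
    "hr_change",
]

LF_BAND = (0.04, 0.15)  # Hz
HF_BAND = (0.15, 0.40)  # Hz


@dataclass(frozen=True)
class HRVParams:
    rr_lo_ms: float = 300.0       # physiologically plausible interval floor
    rr_hi_ms: float = 2000.0      # and ceiling; outside -> artifact
    max_removed_frac: float = 0.20  # more removed -> session unusable
    tachogram_hz: float = 4.0
    welch_segment_s: float = 60.0
    min_duration_s: float = 120.0  # below this, band powers are low-resolution


@dataclass
class CleanResult:
    rr: RRSeries
    n_removed: int
    removed_frac: float
    usable: bool


@dataclass
class Tachogram:
    """Uniformly sampled R-R interval series (ms) at ``fs`` Hz."""

    t: np.ndarray
    rr_ms: np.ndarray
    fs: float

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class HRVMetrics:
    lf_power: float                 # ms^2, 0.04-0.15 Hz
    hf_power: float                 # ms^2, 0.15-0.40 Hz
    lf_hf_ratio: float
    mean_hr: float                  # beats/min
    lf_breathing_coherence: float | None = None
    low_resolution: bool = False


def clean_rr(rr: RRSeries, params: HRVParams | None = None) -> CleanResult:
    """Remove implausible intervals (outside [300, 2000] ms).

    Screens the chest-strap series for detection artifacts; the beat times of
    retained intervals are kept, so the cleaned series stays monotone with
    gaps where beats were dropped.  A session losing more than
    ``max_removed_frac`` of its beats is marked unusable rather than
    repaired.
    """
    params = params or HRVParams()
    keep = (rr.rr >= params.rr_lo_ms) & (rr.rr <= params.rr_hi_ms)
    n_removed = int((~keep).sum())
    frac = n_removed / max(len(rr), 1)
    cleaned = RRSeries(rr.beat_t[keep], rr.rr[keep], cleaned=True)
    return CleanResult(cleaned, n_removed, frac, usable=frac <= params.max_removed_frac)


def rr_to_tachogram(rr: RRSeries, fs: float = 4.0) -> Tachogram:
    """Cubic-spline interpolate rr(beat_t) onto a uniform ``fs`` grid."""
    if len(rr) < 4:
        raise ValueError("need at least 4 beats to build a tachogram")
    spline = CubicSpline(rr.beat_t, rr.rr)
    n = int(np.floor((rr.beat_t[-1] - rr.beat_t[0]) * fs)) + 1
    t = rr.beat_t[0] + np.arange(n) / fs
    return Tachogram(t, spline(t), fs)


def _band_power(freq: np.ndarray, pxx: np.ndarray, band: tuple[float, float]) -> float:
    sel = (freq >= band[0]) & (freq < band[1])
    if not np.any(sel):
        return 0.0
    return float(np.trapezoid(pxx[sel], freq[sel]))


def _welch_nperseg(params: HRVParams, n: int) -> int:
    return min(int(params.welch_segment_s * params.tachogram_hz), n)


def hrv_band_powers(tach: Tachogram, params: HRVParams | None = None) -> HRVMetrics:
    """Band-integrated Welch power of the tachogram plus mean heart rate.

    Mean HR is the time-domain mean, 60000 / mean(rr ms) over the uniform
    grid.  Tachograms shorter than ``min_duration_s`` are still analyzed but
    flagged low-resolution.
    """
    params = params or HRVParams()
    nperseg = _welch_nperseg(params, tach.rr_ms.size)
    freq, pxx = sps.welch(
        tach.rr_ms,
        fs=tach.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    lf = _band_power(freq, pxx, LF_BAND)
    hf = _band_power(freq, pxx, HF_BAND)
    return HRVMetrics(
        lf_power=lf,
        hf_power=hf,
        lf_hf_ratio=lf / hf if hf > 0 else np.inf,
        mean_hr=60000.0 / float(np.mean(tach.rr_ms)),
        low_resolution=tach.duration < params.min_duration_s,
    )


def breathing_lf_coherence(
    breathing: BreathingTrace, tach: Tachogram, params: HRVParams | None = None
) -> float:
    """Mean magnitude-squared coherence of breathing and the tachogram over LF.

    Both series are put on the tachogram's 4 Hz grid restricted to their
    common time support (>= 120 s required so that Welch averages >= 4
    segments; MSC of a single segment is identically 1).  The band mean is
    used rather than the band max: it is the stabler summary and makes the
    1/L estimator bias for independent signals explicit.
    """
    params = params or HRVParams()
    t_lo = max(breathing.t[0], tach.t[0])
    t_hi = min(breathing.t[-1], tach.t[-1])
    if t_hi - t_lo < params.min_duration_s:
        raise ValueError(
            f"common support {t_hi - t_lo:.1f} s < {params.min_duration_s} s"
        )
    n = int(np.floor((t_hi - t_lo) * tach.fs)) + 1
    grid = t_lo + np.arange(n) / tach.fs
    x = np.interp(grid, breathing.t, breathing.y)
    y = np.interp(grid, tach.t, tach.rr_ms)
    nperseg = _welch_nperseg(params, n)
    freq, coh = sps.coherence(
        x, y, fs=tach.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant",
    )
    sel = (freq >= LF_BAND[0]) & (freq <= LF_BAND[1])
    return float(np.mean(coh[sel]))


def _segment_mean_hr(rr: RRSeries) -> float:
    return 60000.0 / float(np.mean(rr.rr))


def hr_change(session: SessionRecord) -> float | None:
    """Mean in-game HR minus mean baseline HR, in beats/min.

    Returns ``None`` (missing) when either R-R segment is absent or flagged.
    """
    if session.flags.rr_missing or session.flags.rr_unusable:
        return None
    if session.baseline_rr is None or session.ingame_rr is None:
        return None
    if len(session.baseline_rr) == 0 or len(session.ingame_rr) == 0:
        return None
    return _segment_mean_hr(session.ingame_rr) - _segment_mean_hr(session.baseline_rr)
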