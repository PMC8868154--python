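"""Sliding-window biofeedback score: spectra, scores, streams, baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathloop.biofeedback import (
    BASELINE_REF_SAMPLES,
    ScoreParams,
    baseline_span_seconds,
    baseline_summary,
    biofeedback_value,
    estimate_breathing_spectrum,
    score_stream,
)
from breathloop.session_model import BiofeedbackStream, BreathingTrace
from breathloop.synthetic import gen_breathing
from oracles import dft_band_score

PARAMS = ScoreParams()
FS = PARAMS.resample_hz


def _segment(freq_hz, amp=1.0, phase=0.0, n=None):
    n = n or PARAMS.nperseg
    t = np.arange(n) / FS
    return amp * np.sin(2 * np.pi * freq_hz * t + phase)


class TestSpectrum:
    def test_sinusoid_peak_at_nearest_grid_frequency(self):
        spec = estimate_breathing_spectrum(_segment(0.1333))
        peak = spec.freq[np.argmax(spec.power)]
        grid = spec.freq[np.argmin(np.abs(spec.freq - 0.1333))]
        assert peak == pytest.approx(grid)

    def test_constant_segment_has_no_power(self):
        spec = estimate_breathing_spectrum(np.full(PARAMS.nperseg, 3.7))
        assert np.sum(spec.power) == pytest.approx(0.0, abs=1e-20)

    def test_total_power_matches_variance(self):
        rng = np.random.default_rng(0)
        y = _segment(0.13) + 0.3 * rng.normal(size=PARAMS.nperseg)
        spec = estimate_breathing_spectrum(y)
        df = spec.freq[1] - spec.freq[0]
        total = np.sum(spec.power) * df
        assert total == pytest.approx(np.var(y), rel=0.05)

    def test_two_tone_band_powers_in_amplitude_squared_ratio(self):
        # tones at 0.12 Hz (amp a) and 0.30 Hz (amp 2a): sinusoid power a^2/2,
        # so the band-integrated powers must come out 1:4
        y = _segment(0.12, amp=1.0) + _segment(0.30, amp=2.0, phase=1.0)
        spec = estimate_breathing_spectrum(y)
        df = spec.freq[1] - spec.freq[0]

        def band_power(lo, hi):
            sel = (spec.freq >= lo) & (spec.freq <= hi)
            return np.sum(spec.power[sel]) * df

        p1 = band_power(0.08, 0.16)
        p2 = band_power(0.26, 0.34)
        assert p1 == pytest.approx(0.5, rel=0.05)
        assert p2 / p1 == pytest.approx(4.0, rel=0.05)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            estimate_breathing_spectrum(np.zeros(100))

    def test_nonfinite_samples_rejected(self):
        y = _segment(0.13)
        y[10] = np.nan
        with pytest.raises(ValueError, match="finite"):
            estimate_breathing_spectrum(y)


class TestScoreValue:
    def test_in_band_sinusoid_scores_high(self):
        rng = np.random.default_rng(1)
        y = _segment(8 / 60) + 0.05 * rng.normal(size=PARAMS.nperseg)
        spec = estimate_breathing_spectrum(y)
        assert biofeedback_value(spec) >= 0.9

    def test_fast_breathing_scores_low(self):
        y = _segment(20 / 60)
        spec = estimate_breathing_spectrum(y)
        score = biofeedback_value(spec)
        oracle = dft_band_score(y, FS, PARAMS.band_lo, PARAMS.band_hi, PARAMS.nfft)
        assert score <= 0.1
        assert score == pytest.approx(oracle, abs=1e-9)

    def test_flat_segment_scores_zero(self):
        spec = estimate_breathing_spectrum(np.full(PARAMS.nperseg, 5.0))
        assert biofeedback_value(spec, signal_scale=25.0) == 0.0

    def test_oracle_equivalence_on_random_segments(self):
        """Band-integration ratio must match an explicit-DFT oracle."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            freq = rng.uniform(0.05, 0.45)
            y = _segment(freq, amp=rng.uniform(0.2, 3.0)) + rng.uniform(
                0.0, 0.5
            ) * rng.normal(size=PARAMS.nperseg)
            spec = estimate_breathing_spectrum(y)
            score = biofeedback_value(spec, signal_scale=float(np.mean(y**2)))
            oracle = dft_band_score(y, FS, PARAMS.band_lo, PARAMS.band_hi, PARAMS.nfft)
            assert score == pytest.approx(oracle, abs=1e-6)


class TestScoreStream:
    def test_60s_trace_yields_16_scores_at_2s_spacing(self):
        trace = gen_breathing(8, 1.0, 60.0, 0)
        stream = score_stream(trace)
        assert len(stream) == 16
        np.testing.assert_allclose(stream.t, 30.0 + 2.0 * np.arange(16))

    def test_stationary_trace_scores_are_stable(self):
        trace = gen_breathing(8, 1.0, 120.0, 3, noise_sd=0.02)
        stream = score_stream(trace)
        assert stream.score.max() - stream.score.min() <= 0.05

    def test_pace_step_transitions_within_one_window(self):
        """After a 20 -> 8 bpm step the score must settle high within 30 s,
        each window agreeing with the DFT oracle along the way."""
        fs = FS
        t = np.arange(int(120 * fs) + 1) / fs
        pace = np.where(t < 60.0, 20.0, 8.0)
        trace = gen_breathing(lambda tt: np.where(tt < 60, 20.0, 8.0), 1.0, 120.0, 0)
        stream = score_stream(trace)
        before = stream.score[stream.t <= 60.0]
        after = stream.score[stream.t >= 90.0 + 2.0]
        assert before.max() <= 0.1
        assert after.min() >= 0.85
        # oracle recomputation of every window in the transition region
        y = trace.y
        for k, t_end in enumerate(stream.t):
            if 60.0 <= t_end <= 92.0:
                seg = y[int((t_end - 30.0) * fs): int(t_end * fs)]
                oracle = dft_band_score(
                    seg, fs, PARAMS.band_lo, PARAMS.band_hi, PARAMS.nfft
                )
                assert stream.score[k] == pytest.approx(oracle, abs=1e-6)

    def test_short_trace_warns_and_returns_empty(self):
        trace = gen_breathing(8, 1.0, 20.0, 0)
        with pytest.warns(UserWarning, match="shorter"):
            stream = score_stream(trace)
        assert len(stream) == 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), seed=st.integers(0, 10**6))
    def test_score_invariant_to_positive_scaling(self, scale, seed):
        """Scaling signal and noise together leaves the pure ratio unchanged."""
        rng = np.random.default_rng(seed)
        y = _segment(rng.uniform(0.06, 0.3)) + 0.2 * rng.normal(size=PARAMS.nperseg)
        s1 = biofeedback_value(estimate_breathing_spectrum(y))
        s2 = biofeedback_value(estimate_breathing_spectrum(scale * y))
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_score_increases_with_depth_under_fixed_noise_floor(self):
        scores = []
        for depth in (0.3, 1.0, 3.0):
            trace = gen_breathing(8, depth, 120.0, 5, noise_sd=0.5)
            scores.append(float(score_stream(trace).score.mean()))
        assert scores[0] < scores[1] < scores[2]

    def test_pace_grid_unimodal_with_peak_in_band(self):
        paces = [4, 6, 8, 10, 14, 20]
        means = []
        for pace in paces:
            trace = gen_breathing(pace, 1.0, 300.0, 11, pace_jitter_sd=1.0, noise_sd=0.25)
            means.append(float(score_stream(trace).score.mean()))
        peak = int(np.argmax(means))
        assert 6 <= paces[peak] <= 10
        tol = 0.02
        for k in range(peak):
            assert means[k] <= means[k + 1] + tol
        for k in range(peak, len(means) - 1):
            assert means[k] + tol >= means[k + 1]


class TestBaselineSummary:
    def test_reference_span_is_56_seconds(self):
        assert baseline_span_seconds(BASELINE_REF_SAMPLES, 0.5) == 56.0

    def test_long_stream_uses_last_29_samples(self):
        scores = np.linspace(0, 1, 40)
        stream = BiofeedbackStream(np.arange(40) * 2.0, scores)
        assert baseline_summary(stream) == pytest.approx(np.mean(scores[11:]))

    def test_exactly_29_samples_uses_all(self):
        scores = np.linspace(0, 1, 29)
        stream = BiofeedbackStream(np.arange(29) * 2.0, scores)
        assert baseline_summary(stream) == pytest.approx(np.mean(scores))

    def test_constant_stream_returns_constant(self):
        stream = BiofeedbackStream(np.arange(35) * 2.0, np.full(35, 0.42))
        assert baseline_summary(stream) == pytest.approx(0.42)

    def test_short_stream_warns(self):
        stream = BiofeedbackStream(np.arange(10) * 2.0, np.full(10, 0.5))
        with pytest.warns(UserWarning, match="baseline"):
            assert baseline_summary(stream) == pytest.approx(0.5)

    def test_empty_stream_raises(self):
        with pytest.raises(ValueError):
            baseline_summary(BiofeedbackStream(np.empty(0), np.empty(0)))
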