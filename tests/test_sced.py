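"""Binning, trends, tau non-overlap contrasts, meta effects, rmcorr."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathloop.sced import (
    BinSeries,
    bin_biofeedback,
    combine_contrasts,
    phase_trend,
    repeated_measures_correlation,
    six_feature_summary,
    subject_contrasts,
    tau_contrast,
)
from breathloop.session_model import BiofeedbackStream, build_phase_design
from oracles import cross_pair_tau, rmcorr_regression_oracle


def _stream(scores, t0=30.0):
    return BiofeedbackStream(t0 + 2.0 * np.arange(len(scores)), scores)


def _bins(values, session_index=1):
    phase = build_phase_design().phase_of_session[session_index]
    return BinSeries(session_index, phase, 15.0 * np.arange(len(values)), np.asarray(values, float))


class TestBinning:
    def test_900s_session_yields_58_bins(self):
        # in-game scores start after the 30 s warm-up; bins anchored at game
        # start, so bins 0-1 are empty and 58 of the 60 remain
        scores = np.random.default_rng(0).uniform(0, 1, 436)
        stream = _stream(scores, t0=30.0)
        bins = bin_biofeedback(stream, t0=0.0)
        assert len(bins) == 58
        assert bins.bin_t[0] == 30.0

    def test_constant_stream_gives_constant_bins(self):
        bins = bin_biofeedback(_stream(np.full(100, 0.6), t0=0.0))
        np.testing.assert_allclose(bins.value, 0.6)

    def test_bin_mean_equals_member_mean_exactly(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0, 1, 120)
        stream = _stream(scores, t0=0.0)
        bins = bin_biofeedback(stream)
        # third kept bin covers [60, 75): samples at t = 60..74 -> indices 30..37
        t = stream.t
        for k, bt in enumerate(bins.bin_t):
            members = scores[(t >= bt) & (t < bt + 15.0)]
            assert bins.value[k] == pytest.approx(np.mean(members), abs=1e-15)

    def test_first_two_bins_discarded(self):
        bins = bin_biofeedback(_stream(np.arange(100) / 100.0, t0=0.0))
        assert bins.bin_t[0] == 30.0

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            bin_biofeedback(_stream(np.full(30, 0.5), t0=0.0))


class TestPhaseTrend:
    def test_linear_bins_recover_slope(self):
        values = 0.01 * np.arange(40)
        slope, _ = phase_trend(values)
        assert slope == pytest.approx(0.01, abs=1e-12)

    def test_constant_bins_zero_slope(self):
        slope, smoothed = phase_trend(np.full(30, 0.4))
        assert slope == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(smoothed, 0.4)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            phase_trend(np.array([0.5]))


class TestTauContrast:
    def test_complete_separation_gives_tau_one(self):
        c = tau_contrast(np.array([0.1, 0.2, 0.3]), np.array([0.4, 0.5, 0.6]))
        assert c.tau == 1.0

    def test_hand_enumerated_example(self):
        # [1,3,2] vs [2,4,5]: C=7, D=1, one tie -> tau = 6/9
        c = tau_contrast(np.array([1.0, 3.0, 2.0]), np.array([2.0, 4.0, 5.0]))
        assert c.tau == pytest.approx(6.0 / 9.0)

    def test_swapping_sessions_flips_sign(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=10), rng.normal(0.5, 1, 12)
        assert tau_contrast(x, y).tau == pytest.approx(-tau_contrast(y, x).tau)

    def test_all_tied_degenerate(self):
        c = tau_contrast(np.full(5, 0.3), np.full(6, 0.3))
        assert c.tau == 0.0 and c.p_value == 1.0 and not c.significant

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(3, 50),
        m=st.integers(3, 50),
        seed=st.integers(0, 10**6),
        ties=st.booleans(),
    )
    def test_matches_exhaustive_pair_enumeration(self, n, m, seed, ties):
        rng = np.random.default_rng(seed)
        if ties:
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, m).astype(float)
        else:
            x, y = rng.normal(size=n), rng.normal(size=m)
        got = tau_contrast(x, y)
        expected, _, _ = cross_pair_tau(x, y)
        assert got.tau == pytest.approx(expected, abs=1e-12)

    def test_tau_b_option_available(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(1.0, 1, 20)
        c = tau_contrast(x, y, variant="tau_b")
        assert -1 <= c.tau <= 1
        # tau-b's ceiling under balanced two-sample ties is below cross-pair 1
        sep = tau_contrast(np.arange(20.0), 100 + np.arange(20.0), variant="tau_b")
        assert sep.tau < 1.0


class TestSubjectContrasts:
    def test_complete_subject_has_eight_contrasts(self):
        rng = np.random.default_rng(4)
        bins = {s: _bins(rng.uniform(0, 1, 20), s) for s in range(1, 11)}
        contrasts = subject_contrasts(bins)
        assert len(contrasts) == 8
        assert sum(c.direction == "addition" for c in contrasts) == 4

    def test_missing_session_marks_adjacent_contrasts(self):
        rng = np.random.default_rng(5)
        bins = {s: _bins(rng.uniform(0, 1, 20), s) for s in range(1, 11) if s != 8}
        contrasts = subject_contrasts(bins)
        missing = {c.pair for c in contrasts if c.missing}
        assert missing == {(7, 8), (8, 9)}

    def test_contrast_phases_match_design(self):
        design = build_phase_design()
        for i, j in design.addition_contrasts:
            assert (design.phase_of_session[i], design.phase_of_session[j]) == ("A", "B")
        for i, j in design.removal_contrasts:
            assert (design.phase_of_session[i], design.phase_of_session[j]) == ("B", "A")


class TestCombine:
    def test_identical_taus_equal_weights(self):
        cs = [
            tau_contrast(np.array([0.0, 0.1, 0.2]), np.array([1.0, 1.1, 1.2]))
            for _ in range(3)
        ]
        meta = combine_contrasts(cs)
        assert meta.combined_tau == pytest.approx(1.0)
        assert meta.k == 3

    def test_single_contrast_is_identity(self):
        rng = np.random.default_rng(6)
        c = tau_contrast(rng.normal(size=10), rng.normal(0.8, 1, 10))
        meta = combine_contrasts([c])
        assert meta.combined_tau == pytest.approx(c.tau)
        assert meta.combined_p == pytest.approx(c.p_value, rel=1e-9)

    def test_pair_count_weighted_mean(self):
        # taus {0.6, 0.2} with pair-count weights {100, 300} -> 0.3
        a = tau_contrast(np.arange(10.0), np.arange(10.0) + 0.5)
        b = tau_contrast(np.arange(15.0), np.arange(20.0))
        a.tau, b.tau = 0.6, 0.2
        a.n_i = a.n_j = 10
        b.n_i, b.n_j = 15, 20
        meta = combine_contrasts([a, b])
        assert meta.combined_tau == pytest.approx(0.3)


class TestSixFeatures:
    def test_two_constant_phases(self):
        bins = {1: _bins(np.full(20, 0.2), 1), 2: _bins(np.full(20, 0.6), 2)}
        contrasts = subject_contrasts(bins)
        summary = six_feature_summary(bins, contrasts)
        fc = summary.changes[0]
        assert fc.level_change == pytest.approx(0.4)
        assert fc.immediacy == pytest.approx(0.4)
        assert fc.trend_change == pytest.approx(0.0, abs=1e-12)

    def test_identical_phases_no_intervention_effect(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0.3, 0.5, 20)
        bins = {s: _bins(base, s) for s in range(1, 11)}
        contrasts = subject_contrasts(bins)
        summary = six_feature_summary(bins, contrasts)
        assert not summary.intervention_effect
        assert summary.feature_change_counts["level"] == 0
        assert summary.feature_change_counts["overlap"] == 0

    def test_strong_boost_triggers_decision(self, learning_cohort):
        from breathloop import pipeline

        records, _ = learning_cohort
        by_subject = {}
        for r in records:
            by_subject.setdefault(r.subject_id, {})[r.session_index] = r
        decisions = []
        for sessions in by_subject.values():
            bins = {i: pipeline.session_bins(r) for i, r in sessions.items()}
            contrasts = subject_contrasts(bins)
            decisions.append(six_feature_summary(bins, contrasts).intervention_effect)
        assert sum(decisions) >= 7


class TestNullCalibration:
    def test_window_overlap_autocorrelation_inflates_pipeline_null_rate(self):
        """Bins of the sliding-window score stream are serially correlated
        (consecutive 30 s windows share up to 28 s of data), so the rank
        test rejects a true null more often through the pipeline than on
        independent bins — a structural property of windowed scoring that
        any bin-level non-overlap test inherits."""
        from breathloop.synthetic import LearningParams, SyntheticCohortConfig, gen_cohort
        from breathloop import pipeline

        cfg = SyntheticCohortConfig(
            n_subjects=100,
            session_s=240.0,
            learning=LearningParams(learning_rate=0.0, bfb_boost=0.0, subject_sd=0.0),
            include_cardiac=False,
            include_events=False,
            seed=88,
        )
        records, _ = gen_cohort(cfg)
        by_subject = {}
        for r in records:
            by_subject.setdefault(r.subject_id, {})[r.session_index] = r
        sig = tot = 0
        n_bins = None
        for sessions in by_subject.values():
            bins = {i: pipeline.session_bins(r) for i, r in sessions.items()}
            n_bins = len(next(iter(bins.values())))
            for c in subject_contrasts(bins):
                if not c.missing:
                    tot += 1
                    sig += c.significant
        pipeline_rate = sig / tot

        rng = np.random.default_rng(88)
        iid_rej = 0
        for _ in range(tot):
            iid_rej += tau_contrast(
                rng.normal(size=n_bins), rng.normal(size=n_bins)
            ).significant
        iid_rate = iid_rej / tot
        assert iid_rate < 0.08
        assert pipeline_rate > iid_rate + 0.02


class TestRmcorr:
    def test_subject_offsets_do_not_mask_perfect_correlation(self):
        x = np.tile(np.arange(10.0), 3)
        offsets = np.repeat([0.0, 5.0, -4.0], 10)
        y = x + offsets
        subjects = np.repeat(["a", "b", "c"], 10)
        res = repeated_measures_correlation(x + offsets * 2, y + offsets * 2, subjects)
        assert res.r == pytest.approx(1.0)

    def test_df_with_missing_sessions(self):
        # 8 subjects x 10 sessions with 3 missing values -> df = 77 - 8 - 1 = 68
        rng = np.random.default_rng(8)
        subjects = np.repeat([f"s{k}" for k in range(8)], 10)
        x = rng.normal(size=80)
        y = 0.5 * x + rng.normal(size=80)
        x[[0, 17, 43]] = np.nan
        res = repeated_measures_correlation(x, y, subjects)
        assert res.n_obs == 77
        assert res.df == 68

    def test_matches_regression_residual_oracle(self):
        rng = np.random.default_rng(9)
        subjects = np.repeat(["a", "b", "c"], 8)
        x = rng.normal(size=24) + np.repeat([0, 3, -2], 8)
        y = 0.7 * x + rng.normal(size=24) + np.repeat([1, -1, 4], 8)
        res = repeated_measures_correlation(x, y, subjects)
        assert res.r == pytest.approx(rmcorr_regression_oracle(x, y, subjects), abs=1e-10)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(10)
        subjects = np.repeat([f"s{k}" for k in range(5)], 9)
        x = rng.normal(size=45) + np.repeat(rng.normal(0, 2, 5), 9)
        y = 0.4 * x + rng.normal(size=45)
        res = repeated_measures_correlation(x, y, subjects)
        df = pd.DataFrame({"x": x, "y": y, "s": subjects})
        ref = pg.rm_corr(data=df, x="x", y="y", subject="s")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.df == int(ref["dof"].iloc[0])
        assert res.p_value == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), shift=st.floats(-50, 50))
    def test_invariant_to_per_subject_constants(self, seed, shift):
        rng = np.random.default_rng(seed)
        subjects = np.repeat(["a", "b", "c", "d"], 6)
        x = rng.normal(size=24)
        y = rng.normal(size=24)
        base = repeated_measures_correlation(x, y, subjects)
        shifted = repeated_measures_correlation(
            x + shift * (subjects == "b"), y - shift * (subjects == "d"), subjects
        )
        assert shifted.r == pytest.approx(base.r, abs=1e-9)

    def test_single_pair_subject_dropped_with_warning(self):
        rng = np.random.default_rng(11)
        subjects = np.array(["a"] * 4 + ["b"] * 4 + ["c"])
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        with pytest.warns(UserWarning, match="dropped"):
            res = repeated_measures_correlation(x, y, subjects)
        assert res.n_subjects == 2
        assert res.n_obs == 8
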