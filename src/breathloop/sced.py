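"""Single-case withdrawal-design statistics on binned biofeedback scores.

The ten-session ABBABABABA design yields eight consecutive-session phase
boundaries per subject: four additions (A->B) and four removals (B->A) of
the biofeedback.  Each session's 0.5 Hz score stream is reduced to 15 s bin
means (the first two in-game bins are discarded to keep baseline-period data
out), and every boundary is tested for non-overlap with a cross-pair
Kendall's tau:

    tau = (C - D) / (n_i * n_j)

over all between-session bin pairs, where C counts pairs with the later
session higher and D the reverse (ties count in neither).  This variant
spans exactly [-1, 1] — complete separation gives |tau| = 1 — unlike the
tie-corrected tau-b whose ceiling for two ~58-bin samples is ~0.71; tau-b is
available as an option.  No baseline (Theil-Sen) trend correction is
applied: within-session trends in these data are typically negative, and
correcting for them would manufacture false positives.  Two-sided p-values
come from the tie-corrected Mann-Whitney normal approximation (the
cross-pair tau is a linear function of the Mann-Whitney U).

Per direction the four contrasts are merged into a meta effect: a
pair-count-weighted mean tau, with a matching weighted Stouffer combination
of signed p-values.  The six visual-analysis features (level, trend,
variability, immediacy, consistency, overlap) and the >=3-changes-in->=3-
features intervention decision are computed alongside, and repeated-measures
correlation links per-session metrics across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .session_model import BiofeedbackStream, PhaseDesign, build_phase_design

__all__ = [
    "BinSeries",
    "TauContrast",
    "MetaEffect",
    "RmcorrResult",
    "FeatureChange",
    "SixFeatureSummary",
    "bin_biofeedback",
    "phase_trend",
    "tau_contrast",
    "subject_contrasts",
    "combine_contrasts",
    "six_feature_summary",
    "repeated_measures_correlation",
]

BIN_SECONDS = 15.0
N_DISCARDED_BINS = 2  # leading bins dropped to exclude baseline-period data
ALPHA = 0.05


@dataclass
class BinSeries:
    """15 s bin means of one session's biofeedback stream."""

    session_index: int
    phase: str
    bin_t: np.ndarray
    value: np.ndarray

    def __len__(self) -> int:
        return int(self.value.size)


@dataclass
class TauContrast:
    pair: tuple[int, int]
    direction: str            # "addition" or "removal"
    tau: float | None
    p_value: float | None
    n_i: int
    n_j: int
    significant: bool | None
    missing: bool = False


@dataclass
class MetaEffect:
    direction: str
    combined_tau: float
    combined_p: float
    k: int


@dataclass
class RmcorrResult:
    r: float
    df: int
    p_value: float
    n_obs: int
    n_subjects: int


def bin_biofeedback(
    stream: BiofeedbackStream,
    bin_s: float = BIN_SECONDS,
    n_discard: int = N_DISCARDED_BINS,
    session_index: int = 0,
    phase: str = "",
    t0: float | None = None,
) -> BinSeries:
    """Average a score stream into consecutive 15 s bins, dropping the first two.

    Bins are time-based half-open intervals [t0 + k*bin, t0 + (k+1)*bin)
    anchored at the stream start (or an explicit in-game ``t0``); each value
    is the mean of its member samples and empty trailing bins are dropped.
    """
    if len(stream) == 0:
        raise ValueError("empty biofeedback stream")
    start = stream.t[0] if t0 is None else t0
    # only complete 15 s bins: a lone sample exactly at the session end must
    # not open a trailing sliver bin
    n_bins = int(np.floor((stream.t[-1] - start) / bin_s + 1e-9))
    if n_bins < 1:
        raise ValueError("stream shorter than one bin")
    idx = np.floor((stream.t - start) / bin_s + 1e-9).astype(int)
    valid = (idx >= 0) & (idx < n_bins)
    idx, scores = idx[valid], stream.score[valid]
    sums = np.bincount(idx, weights=scores, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    present = counts > 0
    means = np.full(n_bins, np.nan)
    means[present] = sums[present] / counts[present]
    keep = present.copy()
    keep[:n_discard] = False
    if keep.sum() < 3:
        raise ValueError(f"only {int(keep.sum())} usable bins (< 3) after trimming")
    bin_t = start + bin_s * np.flatnonzero(keep)
    return BinSeries(session_index, phase, bin_t, means[keep])


def phase_trend(values: np.ndarray, ma_window: int = 5) -> tuple[float, np.ndarray]:
    """Degree-1 least-squares slope (per bin) plus a moving-average curve.

    ``values`` are bin means concatenated across all sessions of one phase,
    in session order; the smoothed curve (centered moving average, shrinking
    windows at the edges) is for display.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 bins to fit a trend")
    x = np.arange(y.size, dtype=float)
    slope = float(np.polyfit(x, y, 1)[0])
    half = ma_window // 2
    smoothed = np.array(
        [np.mean(y[max(0, i - half): i + half + 1]) for i in range(y.size)]
    )
    return slope, smoothed


def _cross_pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int]:
    """Concordant (later higher), discordant, tied cross-pair counts."""
    diff = y[None, :] - x[:, None]
    c = int(np.count_nonzero(diff > 0))
    d = int(np.count_nonzero(diff < 0))
    t = x.size * y.size - c - d
    return c, d, t


def _mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def tau_contrast(
    bins_i: BinSeries | np.ndarray,
    bins_j: BinSeries | np.ndarray,
    direction: str = "addition",
    alpha: float = ALPHA,
    variant: str = "cross_pair",
) -> TauContrast:
    """Non-overlap of two consecutive sessions' bins via cross-pair tau.

    Positive tau means the later session runs higher.  ``variant`` selects
    the default exactly-[-1, 1] cross-pair tau or the tie-corrected
    ``"tau_b"`` Kendall coefficient (computed on the pooled values against a
    session indicator).  Degenerate input (every value tied) yields tau 0,
    p 1.
    """
    x = np.asarray(bins_i.value if isinstance(bins_i, BinSeries) else bins_i, float)
    y = np.asarray(bins_j.value if isinstance(bins_j, BinSeries) else bins_j, float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each session needs at least 3 bins")
    pair = (
        (bins_i.session_index, bins_j.session_index)
        if isinstance(bins_i, BinSeries) and isinstance(bins_j, BinSeries)
        else (0, 0)
    )
    if np.all(x == x[0]) and np.all(y == x[0]):
        return TauContrast(pair, direction, 0.0, 1.0, x.size, y.size, False)
    if variant == "cross_pair":
        c, d, _ = _cross_pair_counts(x, y)
        tau = (c - d) / (x.size * y.size)
    elif variant == "tau_b":
        pooled = np.concatenate([x, y])
        group = np.concatenate([np.zeros(x.size), np.ones(y.size)])
        tau = float(stats.kendalltau(group, pooled).statistic)
    else:
        raise ValueError(f"unknown tau variant {variant!r}")
    p = _mann_whitney_p(x, y)
    return TauContrast(pair, direction, float(tau), p, x.size, y.size, p < alpha)


def subject_contrasts(
    bins_by_session: dict[int, BinSeries],
    design: PhaseDesign | None = None,
    alpha: float = ALPHA,
    variant: str = "cross_pair",
) -> list[TauContrast]:
    """All 4 addition + 4 removal contrasts of one subject, in design order.

    A contrast whose sessions are not both present is reported as missing
    (mirroring dropped sessions in real cohorts), never silently skipped.
    """
    design = design or build_phase_design()
    out: list[TauContrast] = []
    for direction, pairs in (
        ("addition", design.addition_contrasts),
        ("removal", design.removal_contrasts),
    ):
        for i, j in pairs:
            if i not in bins_by_session or j not in bins_by_session:
                out.append(TauContrast((i, j), direction, None, None, 0, 0, None, missing=True))
                continue
            out.append(
                tau_contrast(bins_by_session[i], bins_by_session[j], direction, alpha, variant)
            )
    return out


def combine_contrasts(contrasts: list[TauContrast]) -> MetaEffect:
    """Merge same-direction contrasts into one meta effect.

    The combined tau is the pair-count-weighted (w = n_i * n_j) mean of the
    contrast taus; the combined p applies Stouffer's weighted method to the
    signed contrast z-scores (sign carried by tau).
    """
    live = [c for c in contrasts if not c.missing]
    if not live:
        raise ValueError("no non-missing contrasts to combine")
    directions = {c.direction for c in live}
    if len(directions) != 1:
        raise ValueError("contrasts must share one direction")
    w = np.array([c.n_i * c.n_j for c in live], dtype=float)
    taus = np.array([c.tau for c in live])
    combined_tau = float(np.sum(w * taus) / np.sum(w))
    z = np.array(
        [np.sign(c.tau) * stats.norm.isf(min(c.p_value, 1.0) / 2.0) for c in live]
    )
    z_comb = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    combined_p = float(2.0 * stats.norm.sf(abs(z_comb)))
    return MetaEffect(live[0].direction, combined_tau, combined_p, len(live))


# ---------------------------------------------------------------------------
# six-feature visual-analysis summary
# ---------------------------------------------------------------------------

@dataclass
class FeatureChange:
    """Feature values at one phase change, with per-feature change verdicts."""

    pair: tuple[int, int]
    direction: str
    level_change: float        # mean(new) - mean(old)
    trend_change: float        # slope(new) - slope(old), per bin
    variability_ratio: float   # SD(new) / SD(old)
    immediacy: float           # mean(first 3 new bins) - mean(last 3 old bins)
    overlap_significant: bool  # tau contrast significant in expected direction
    changed: dict[str, bool] | None = None


@dataclass
class SixFeatureSummary:
    changes: list[FeatureChange]
    consistency: dict[str, float]        # within-direction SD of phase means
    feature_change_counts: dict[str, int]
    intervention_effect: bool


#: minimum magnitudes for a phase change to count as a "change" per feature;
#: conventional visual-analysis operationalizations on a [0, 1] score scale
CHANGE_THRESHOLDS = {
    "level": 0.05,        # score units
    "trend": 0.002,       # score units per 15 s bin
    "variability": 1.25,  # SD ratio (or its reciprocal)
}


def _expected_sign(direction: str) -> float:
    return 1.0 if direction == "addition" else -1.0


def six_feature_summary(
    bins_by_session: dict[int, BinSeries],
    contrasts: list[TauContrast],
    design: PhaseDesign | None = None,
    thresholds: dict[str, float] | None = None,
    min_changes: int = 3,
    min_features: int = 3,
) -> SixFeatureSummary:
    """Level/trend/variability/immediacy/consistency/overlap per phase change.

    A feature registers a "change" at a phase boundary when it moves in the
    direction the intervention predicts (addition raises the score, removal
    lowers it) by at least the documented threshold; overlap registers when
    the tau contrast is significant with the expected sign.  The intervention
    decision requires at least ``min_changes`` changes on at least
    ``min_features`` of the six features.  Consistency — the within-direction
    spread of phase means — is reported descriptively per phase type.
    """
    design = design or build_phase_design()
    thr = {**CHANGE_THRESHOLDS, **(thresholds or {})}
    by_pair = {c.pair: c for c in contrasts}
    changes: list[FeatureChange] = []
    for direction, pairs in (
        ("addition", design.addition_contrasts),
        ("removal", design.removal_contrasts),
    ):
        sign = _expected_sign(direction)
        for i, j in pairs:
            if i not in bins_by_session or j not in bins_by_session:
                continue
            old, new = bins_by_session[i].value, bins_by_session[j].value
            slope_old, _ = phase_trend(old)
            slope_new, _ = phase_trend(new)
            sd_old, sd_new = float(np.std(old, ddof=1)), float(np.std(new, ddof=1))
            fc = FeatureChange(
                pair=(i, j),
                direction=direction,
                level_change=float(np.mean(new) - np.mean(old)),
                trend_change=slope_new - slope_old,
                variability_ratio=sd_new / sd_old if sd_old > 0 else np.inf,
                immediacy=float(np.mean(new[:3]) - np.mean(old[-3:])),
                overlap_significant=bool(
                    (c := by_pair.get((i, j))) is not None
                    and not c.missing
                    and c.significant
                    and np.sign(c.tau) == sign
                ),
            )
            ratio = fc.variability_ratio
            fc.changed = {
                "level": sign * fc.level_change >= thr["level"],
                "trend": sign * fc.trend_change >= thr["trend"],
                "variability": bool(
                    np.isfinite(ratio)
                    and (ratio >= thr["variability"] or ratio <= 1 / thr["variability"])
                ),
                "immediacy": sign * fc.immediacy >= thr["level"],
                "overlap": fc.overlap_significant,
            }
            changes.append(fc)

    phase_means = {
        ph: [float(np.mean(b.value)) for b in bins_by_session.values() if b.phase == ph]
        for ph in ("A", "B")
    }
    consistency = {
        ph: float(np.std(v, ddof=1)) if len(v) >= 2 else np.nan
        for ph, v in phase_means.items()
    }
    # consistency registers once per phase type: phases of one type cluster
    # more tightly than the A-vs-B separation they straddle
    gap = abs(np.mean(phase_means["B"]) - np.mean(phase_means["A"])) if all(
        phase_means.values()
    ) else 0.0
    consistency_changes = sum(
        1 for ph in ("A", "B")
        if np.isfinite(consistency[ph]) and consistency[ph] < gap
    )
    counts = {
        feat: sum(1 for fc in changes if fc.changed[feat])
        for feat in ("level", "trend", "variability", "immediacy", "overlap")
    }
    counts["consistency"] = consistency_changes
    n_features_changed = sum(1 for v in counts.values() if v >= min_changes)
    return SixFeatureSummary(
        changes=changes,
        consistency=consistency,
        feature_change_counts=counts,
        intervention_effect=n_features_changed >= min_features,
    )


def repeated_measures_correlation(
    x, y, subjects, alpha: float = ALPHA
) -> RmcorrResult:
    """Common within-subject correlation of paired per-session measurements.

    Both variables are centered on their subject means and the pooled
    residuals correlated; the degrees of freedom, df = n_obs - n_subjects -
    1, account for the subject intercepts, and the p-value comes from the t
    distribution on df.  Pairs with a missing member are dropped listwise;
    subjects left with fewer than 2 complete pairs are dropped with a
    warning (a single pair carries no within-subject information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    if not (x.size == y.size == subjects.size):
        raise ValueError("x, y and subjects must have equal length")
    complete = np.isfinite(x) & np.isfinite(y)
    x, y, subjects = x[complete], y[complete], subjects[complete]
    keep = np.ones(x.size, dtype=bool)
    for s in np.unique(subjects):
        sel = subjects == s
        if sel.sum() < 2:
            warnings.warn(f"subject {s!r} has < 2 complete pairs; dropped")
            keep[sel] = False
    x, y, subjects = x[keep], y[keep], subjects[keep]
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ValueError("need at least 2 subjects with >= 2 complete pairs")
    xr = x.copy()
    yr = y.copy()
    for s in uniq:
        sel = subjects == s
        xr[sel] -= xr[sel].mean()
        yr[sel] -= yr[sel].mean()
    denom = np.sqrt(np.sum(xr**2) * np.sum(yr**2))
    if denom == 0:
        raise ValueError("degenerate data: no within-subject variance")
    r = float(np.sum(xr * yr) / denom)
    n_obs = int(x.size)
    df = n_obs - int(uniq.size) - 1
    r_clip = min(abs(r), 1 - 1e-15)
    t = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = float(2.0 * stats.t.sf(t, df))
    return RmcorrResult(r=r, df=df, p_value=p, n_obs=n_obs, n_subjects=int(uniq.size))
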