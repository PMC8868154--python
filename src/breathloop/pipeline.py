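"""Per-session metric extraction and cohort-level reporting.

``session_metrics`` composes the stage operations — biofeedback summary,
HRV band powers and coherence, behavioral tallies and signal-detection
indices — into one tidy row per subject-session; flagged-missing streams
propagate as empty (NaN) fields, never zeros.  ``cohort_report`` runs the
whole cohort and writes the analysis tables: the per-session metrics, the
withdrawal-design contrast table (subjects x S1-S2 ... S9-S10 + meta,
addition then removal), repeated-measures correlations of the session-mean
biofeedback score against the HRV metrics, and the six-feature summaries
with per-subject intervention decisions.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import behavior, biofeedback, hrv, sced
from .session_model import SessionRecord, build_phase_design

__all__ = ["PipelineParams", "session_metrics", "session_bins", "rmcorr_table", "cohort_report"]

log = logging.getLogger("breathloop")


@dataclass(frozen=True)
class PipelineParams:
    score: biofeedback.ScoreParams = field(default_factory=biofeedback.ScoreParams)
    hrv: hrv.HRVParams = field(default_factory=hrv.HRVParams)
    alpha: float = sced.ALPHA
    tau_variant: str = "cross_pair"
    recompute_scores: bool = False  # re-derive scores from the breathing trace
    #: subjects excluded from HRV-dependent analyses (e.g. unreliable R-peak
    #: detection); their behavioral and score metrics are still reported
    hrv_excluded_subjects: tuple[str, ...] = ()


def _ingame_score(record: SessionRecord, params: PipelineParams):
    if params.recompute_scores and record.ingame_breathing is not None:
        return biofeedback.score_stream(record.ingame_breathing, params.score)
    return record.ingame_score


def session_metrics(record: SessionRecord, params: PipelineParams | None = None) -> dict:
    """One flat metrics row for a session; missing stages yield NaN fields."""
    params = params or PipelineParams()
    row: dict = {
        "subject_id": record.subject_id,
        "session_index": record.session_index,
        "phase": record.phase,
    }
    nan = float("nan")

    score = _ingame_score(record, params)
    if score is not None and len(score):
        row["mean_biofeedback"] = float(np.mean(score.score))
        row["control_of_self"] = behavior.control_of_self(score)
        if record.self_rating_control_of_self is not None:
            row["awareness"] = behavior.awareness_score(
                row["control_of_self"], record.self_rating_control_of_self
            )
        else:
            row["awareness"] = nan
    else:
        row.update(mean_biofeedback=nan, control_of_self=nan, awareness=nan)
    if record.baseline_score is not None and len(record.baseline_score):
        row["baseline_biofeedback"] = biofeedback.baseline_summary(record.baseline_score)
    else:
        row["baseline_biofeedback"] = nan

    hrv_fields = ("lf_power", "hf_power", "lf_hf_ratio", "lf_breathing_coherence", "mean_hr")
    rr_ok = (
        record.ingame_rr is not None
        and not record.flags.rr_missing
        and not record.flags.rr_unusable
    )
    if rr_ok:
        clean = hrv.clean_rr(record.ingame_rr, params.hrv)
        if clean.usable and len(clean.rr) >= 4:
            tach = hrv.rr_to_tachogram(clean.rr, params.hrv.tachogram_hz)
            metrics = hrv.hrv_band_powers(tach, params.hrv)
            row["lf_power"] = metrics.lf_power
            row["hf_power"] = metrics.hf_power
            row["lf_hf_ratio"] = metrics.lf_hf_ratio
            row["mean_hr"] = metrics.mean_hr
            if record.ingame_breathing is not None:
                row["lf_breathing_coherence"] = hrv.breathing_lf_coherence(
                    record.ingame_breathing, tach, params.hrv
                )
            else:
                row["lf_breathing_coherence"] = nan
            change = hrv.hr_change(record)
            row["hr_change"] = nan if change is None else change
        else:
            row.update({f: nan for f in hrv_fields}, hr_change=nan)
            row["rr_unusable"] = True
    else:
        row.update({f: nan for f in hrv_fields}, hr_change=nan)

    if record.events:
        counts = behavior.tally_events(record.events)
        row.update(
            hits=counts.hits,
            misses=counts.misses,
            false_alarms=counts.false_alarms,
            correct_rejections=counts.correct_rejections,
        )
        if counts.hostile_total >= 1 and counts.friendly_total >= 1:
            sdt = behavior.sdt_metrics(counts)
            row.update(
                hit_rate=sdt.hit_rate, fa_rate=sdt.fa_rate,
                d_prime=sdt.d_prime, criterion=sdt.criterion,
            )
        diff = behavior.priming_fa_difference(counts)
        row["priming_fa_diff"] = nan if diff is None else diff
    return row


def session_bins(record: SessionRecord, params: PipelineParams | None = None):
    """15 s bin means of the in-game score stream, or ``None`` if missing."""
    params = params or PipelineParams()
    score = _ingame_score(record, params)
    if score is None or len(score) == 0:
        return None
    return sced.bin_biofeedback(
        score,
        session_index=record.session_index,
        phase=record.phase,
        t0=record.game_start_t,
    )


def _contrast_table(
    records_by_subject: dict[str, dict[int, SessionRecord]],
    params: PipelineParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    design = build_phase_design()
    contrast_rows, feature_rows, decision_rows = [], [], []
    for subject_id, sessions in records_by_subject.items():
        bins = {}
        for s_idx, rec in sessions.items():
            b = session_bins(rec, params)
            if b is not None:
                bins[s_idx] = b
        contrasts = sced.subject_contrasts(bins, design, params.alpha, params.tau_variant)
        for direction in ("addition", "removal"):
            row: dict = {"subject_id": subject_id, "direction": direction}
            dir_contrasts = [c for c in contrasts if c.direction == direction]
            for c in dir_contrasts:
                col = f"S{c.pair[0]}-S{c.pair[1]}"
                row[col] = np.nan if c.missing else c.tau
                row[col + "_p"] = np.nan if c.missing else c.p_value
                row[col + "_sig"] = "" if c.missing or not c.significant else "*"
            live = [c for c in dir_contrasts if not c.missing]
            if live:
                meta = sced.combine_contrasts(live)
                row["meta_tau"] = meta.combined_tau
                row["meta_p"] = meta.combined_p
                row["meta_sig"] = "*" if meta.combined_p < params.alpha else ""
            contrast_rows.append(row)
        summary = sced.six_feature_summary(bins, contrasts, design)
        for fc in summary.changes:
            feature_rows.append(
                {
                    "subject_id": subject_id,
                    "pair": f"S{fc.pair[0]}-S{fc.pair[1]}",
                    "direction": fc.direction,
                    "level_change": fc.level_change,
                    "trend_change": fc.trend_change,
                    "variability_ratio": fc.variability_ratio,
                    "immediacy": fc.immediacy,
                    "overlap_significant": fc.overlap_significant,
                }
            )
        decision_rows.append(
            {
                "subject_id": subject_id,
                **{f"n_changes_{k}": v for k, v in summary.feature_change_counts.items()},
                "intervention_effect": summary.intervention_effect,
            }
        )
    return (
        pd.DataFrame(contrast_rows),
        pd.DataFrame(feature_rows),
        pd.DataFrame(decision_rows),
    )


def rmcorr_table(metrics: pd.DataFrame, params: PipelineParams) -> pd.DataFrame:
    rows = []
    usable = metrics[~metrics["subject_id"].isin(params.hrv_excluded_subjects)]
    for target in ("lf_breathing_coherence", "lf_power", "hf_power"):
        sub = usable[["subject_id", "mean_biofeedback", target]]
        try:
            res = sced.repeated_measures_correlation(
                sub["mean_biofeedback"], sub[target], sub["subject_id"]
            )
            rows.append(
                {
                    "x": "mean_biofeedback",
                    "y": target,
                    "r": res.r,
                    "df": res.df,
                    "p_value": res.p_value,
                    "n_obs": res.n_obs,
                    "n_subjects": res.n_subjects,
                }
            )
        except ValueError as exc:
            log.warning("rmcorr %s skipped: %s", target, exc)
    return pd.DataFrame(rows)


def cohort_report(
    records: Sequence[SessionRecord],
    params: PipelineParams | None = None,
    outdir=None,
) -> dict[str, pd.DataFrame]:
    """Run the full analysis over a cohort; optionally write the CSV bundle.

    Returns (and writes, when ``outdir`` is given) ``metrics``,
    ``contrasts`` (the withdrawal-design table), ``rmcorr``, ``features``
    and ``decisions`` tables.  Session records are never mutated.
    """
    params = params or PipelineParams()
    if not records:
        raise ValueError("empty cohort")
    t0 = time.perf_counter()
    metrics = pd.DataFrame([session_metrics(r, params) for r in records])
    log.info("session metrics: %.1f s", time.perf_counter() - t0)

    by_subject: dict[str, dict[int, SessionRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, {})[r.session_index] = r
    t0 = time.perf_counter()
    contrasts, features, decisions = _contrast_table(by_subject, params)
    log.info("withdrawal contrasts: %.1f s", time.perf_counter() - t0)
    rmcorr = rmcorr_table(metrics, params)

    tables = {
        "metrics": metrics,
        "contrasts": contrasts,
        "rmcorr": rmcorr,
        "features": features,
        "decisions": decisions,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            # metrics keep full precision; report tables round to 4 decimals
            if name == "metrics":
                df.to_csv(outdir / f"{name}.csv", index=False)
            else:
                df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.4f")
    return tables
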