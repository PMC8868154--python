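"""Session-level behavioral metrics from the shoot/don't-shoot event log.

Shoot decisions on hostile vs friendly targets form a detection problem:
hits and misses partition resolved hostile targets, false alarms and
correct rejections the friendly ones.  Sensitivity and response bias follow
equal-variance signal detection theory,

    d' = z(H) - z(F),        c = -[z(H) + z(F)] / 2,

with a loglinear (Hautus) correction — 0.5 added to every count, 1 to every
denominator — applied unconditionally so that sessions with no false alarms
still yield finite z-scores.

Priming (dispatch announcing a hostile body type) is summarized as the raw
false-alarm-rate difference between primed and unprimed friendly targets.
"Control of the self" is the share of the session spent with a biofeedback
score of at least 0.8; awareness is the signed gap between that actual
score and the subject's self-rating (negative = overestimation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.stats import norm

from .session_model import BiofeedbackStream, GameEvent, ValidationError

__all__ = [
    "OutcomeCounts",
    "SDTMetrics",
    "tally_events",
    "sdt_metrics",
    "priming_fa_difference",
    "control_of_self",
    "awareness_score",
    "CONTROL_OF_SELF_THRESHOLD",
]

CONTROL_OF_SELF_THRESHOLD = 0.8


@dataclass(frozen=True)
class OutcomeCounts:
    """Exhaustive tally of resolved targets, stratified by priming."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    hits_primed: int = 0
    misses_primed: int = 0
    false_alarms_primed: int = 0
    correct_rejections_primed: int = 0

    @property
    def hostile_total(self) -> int:
        return self.hits + self.misses

    @property
    def friendly_total(self) -> int:
        return self.false_alarms + self.correct_rejections

    def stratum(self, primed: bool) -> "OutcomeCounts":
        """Counts restricted to one priming stratum."""
        if primed:
            return OutcomeCounts(
                self.hits_primed,
                self.misses_primed,
                self.false_alarms_primed,
                self.correct_rejections_primed,
            )
        return OutcomeCounts(
            self.hits - self.hits_primed,
            self.misses - self.misses_primed,
            self.false_alarms - self.false_alarms_primed,
            self.correct_rejections - self.correct_rejections_primed,
        )


@dataclass(frozen=True)
class SDTMetrics:
    hit_rate: float       # loglinear-corrected, strictly inside (0, 1)
    fa_rate: float
    d_prime: float
    criterion: float


_KIND_FIELD = {
    "shot_hit": "hits",
    "miss_reached": "misses",
    "shot_false_alarm": "false_alarms",
    "correct_rejection": "correct_rejections",
}


def tally_events(events: Iterable[GameEvent]) -> OutcomeCounts:
    """Sum events into mutually exclusive outcome counts (+ primed strata)."""
    totals = dict.fromkeys(_KIND_FIELD.values(), 0)
    primed = dict.fromkeys(_KIND_FIELD.values(), 0)
    for ev in events:
        try:
            fieldname = _KIND_FIELD[ev.kind]
        except KeyError:
            raise ValidationError(f"unknown event kind {ev.kind!r}") from None
        totals[fieldname] += 1
        if ev.primed:
            primed[fieldname] += 1
    return OutcomeCounts(
        **totals, **{f"{k}_primed": v for k, v in primed.items()}
    )


def sdt_metrics(counts: OutcomeCounts) -> SDTMetrics:
    """Loglinear-corrected hit/FA rates, sensitivity d' and criterion c."""
    if counts.hostile_total < 1 or counts.friendly_total < 1:
        raise ValueError("need at least one hostile and one friendly target")
    hit_rate = (counts.hits + 0.5) / (counts.hostile_total + 1)
    fa_rate = (counts.false_alarms + 0.5) / (counts.friendly_total + 1)
    zh, zf = norm.ppf(hit_rate), norm.ppf(fa_rate)
    return SDTMetrics(
        hit_rate=float(hit_rate),
        fa_rate=float(fa_rate),
        d_prime=float(zh - zf),
        criterion=float(-(zh + zf) / 2.0),
    )


def priming_fa_difference(counts: OutcomeCounts) -> float | None:
    """FA rate (primed) - FA rate (unprimed), raw proportions.

    Requires at least one friendly target in each stratum; otherwise the
    difference is undefined and ``None`` (missing) is returned.
    """
    p = counts.stratum(True)
    u = counts.stratum(False)
    if p.friendly_total < 1 or u.friendly_total < 1:
        return None
    return p.false_alarms / p.friendly_total - u.false_alarms / u.friendly_total


def control_of_self(
    stream: BiofeedbackStream, threshold: float = CONTROL_OF_SELF_THRESHOLD
) -> float:
    """Percent of the (post-warm-up) session with score >= ``threshold``."""
    if len(stream) == 0:
        raise ValueError("empty biofeedback stream")
    return 100.0 * float(np.mean(stream.score >= threshold))


def awareness_score(actual_percent: float, reported_percent: float) -> float:
    """Actual minus self-reported control-of-self, both on a 0-100 scale.

    Negative values mean the subject overestimated their breathing control.
    """
    for name, v in (("actual", actual_percent), ("reported", reported_percent)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} score {v} outside [0, 100]")
    return float(actual_percent - reported_percent)
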