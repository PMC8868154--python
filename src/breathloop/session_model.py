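"""Domain types, session-log I/O, and withdrawal-design bookkeeping.

A training cohort follows a ten-session ABBABABABA withdrawal design: the
intervention (online breathing biofeedback) is absent in A sessions
(1, 4, 6, 8, 10) and present in B sessions (2, 3, 5, 7, 9).  Each
subject-session is one :class:`SessionRecord` holding the physiological
streams recorded before the game (baseline) and during it, the game event
log, and the post-session self-rating.

Time convention: ``t = 0`` at the start of the recorded baseline; the game
start is stored explicitly so baseline and in-game segments share one clock.
Missing streams are represented explicitly in :class:`SessionFlags` and are
never silently imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BreathingTrace",
    "RRSeries",
    "BiofeedbackStream",
    "GameEvent",
    "SessionFlags",
    "SessionRecord",
    "PhaseDesign",
    "ValidationError",
    "build_phase_design",
    "load_session",
    "save_session",
    "export_streams_csv",
    "read_manifest",
    "write_manifest",
]

EVENT_KINDS = ("shot_hit", "miss_reached", "shot_false_alarm", "correct_rejection")
BODY_TYPES = ("tall_male", "small_male", "tall_female", "small_female")
EYE_COLORS = ("red", "blue", "yellow")

#: relative tolerance for the rr[i] ~ diff(beat_t) consistency check
_RR_CONSISTENCY_TOL_MS = 2.0


class ValidationError(ValueError):
    """Raised when a record or stream violates its invariants."""


def _as_float_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(a)):
        raise ValidationError(f"{name} contains non-finite values")
    return a


@dataclass
class BreathingTrace:
    """Respiration-belt amplitude samples.

    Parameters
    ----------
    t : array
        Seconds from session start, strictly increasing.
    y : array
        Belt amplitude (arbitrary units).
    rate : float
        Nominal samples per second of the recording (belts differ, so the
        rate travels with the trace rather than being assumed).
    """

    t: np.ndarray
    y: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "BreathingTrace.t")
        self.y = _as_float_array(self.y, "BreathingTrace.y")
        if self.t.size != self.y.size:
            raise ValidationError("BreathingTrace: t and y lengths differ")
        if self.t.size < 2:
            raise ValidationError("BreathingTrace: need at least 2 samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValidationError("BreathingTrace: t must be strictly increasing")
        if not self.rate > 0:
            raise ValidationError("BreathingTrace: rate must be positive")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class RRSeries:
    """R-peak times (s) with the inter-beat interval (ms) ending at each beat."""

    beat_t: np.ndarray
    rr: np.ndarray
    #: set after artifact screening; relaxes the rr-vs-beat-gap consistency check
    cleaned: bool = False

    def __post_init__(self) -> None:
        self.beat_t = _as_float_array(self.beat_t, "RRSeries.beat_t")
        self.rr = _as_float_array(self.rr, "RRSeries.rr")
        if self.beat_t.size != self.rr.size:
            raise ValidationError("RRSeries: beat_t and rr lengths differ")
        if self.beat_t.size and not np.all(np.diff(self.beat_t) > 0):
            raise ValidationError("RRSeries: beat_t must be strictly increasing")
        if self.beat_t.size and not np.all(self.rr > 0):
            raise ValidationError("RRSeries: rr must be positive")
        if not self.cleaned and self.beat_t.size >= 2:
            gaps_ms = np.diff(self.beat_t) * 1000.0
            if np.max(np.abs(gaps_ms - self.rr[1:])) > _RR_CONSISTENCY_TOL_MS:
                raise ValidationError(
                    "RRSeries: rr inconsistent with beat_t gaps "
                    f"(tolerance {_RR_CONSISTENCY_TOL_MS} ms)"
                )

    def __len__(self) -> int:
        return int(self.beat_t.size)

    @property
    def duration(self) -> float:
        return float(self.beat_t[-1] - self.beat_t[0])


@dataclass
class BiofeedbackStream:
    """The 0.5 Hz biofeedback score series; scores live in [0, 1]."""

    t: np.ndarray
    score: np.ndarray

    SPACING = 2.0  # seconds between scores (0.5 Hz update rate)

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "BiofeedbackStream.t")
        self.score = _as_float_array(self.score, "BiofeedbackStream.score")
        if self.t.size != self.score.size:
            raise ValidationError("BiofeedbackStream: t and score lengths differ")
        if self.score.size and (self.score.min() < 0 or self.score.max() > 1):
            raise ValidationError("BiofeedbackStream: scores must lie in [0, 1]")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.max(np.abs(dt - self.SPACING)) > 1e-6:
                raise ValidationError("BiofeedbackStream: spacing must be 2 s")

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass
class GameEvent:
    """One resolved target in the shoot/don't-shoot game.

    ``kind`` must agree with ``hostile``: hostile targets resolve as
    ``shot_hit`` or ``miss_reached``; friendly targets as
    ``shot_false_alarm`` or ``correct_rejection``.  ``primed`` marks targets
    whose body type matched the dispatch description of the hostiles.
    """

    t: float
    kind: str
    body_type: str
    primed: bool
    eye_color: str
    hostile: bool
    wave: int
    distance: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"GameEvent: unknown kind {self.kind!r}")
        if self.body_type not in BODY_TYPES:
            raise ValidationError(f"GameEvent: unknown body_type {self.body_type!r}")
        if self.eye_color not in EYE_COLORS:
            raise ValidationError(f"GameEvent: unknown eye_color {self.eye_color!r}")
        if not 1 <= self.wave <= 14:
            raise ValidationError(f"GameEvent: wave {self.wave} outside 1..14")
        hostile_kind = self.kind in ("shot_hit", "miss_reached")
        if hostile_kind != bool(self.hostile):
            raise ValidationError(
                f"GameEvent: kind {self.kind!r} inconsistent with hostile={self.hostile}"
            )


@dataclass
class SessionFlags:
    """Explicit missing-data markers; downstream analyses drop flagged streams."""

    rr_missing: bool = False
    breathing_missing: bool = False
    score_missing: bool = False
    rr_unusable: bool = False  # artifact screening removed too many beats


@dataclass
class SessionRecord:
    """One subject-session of the withdrawal design."""

    subject_id: str
    session_index: int
    phase: str
    game_start_t: float
    baseline_score: BiofeedbackStream | None = None
    baseline_rr: RRSeries | None = None
    ingame_breathing: BreathingTrace | None = None
    ingame_rr: RRSeries | None = None
    ingame_score: BiofeedbackStream | None = None
    events: list[GameEvent] = field(default_factory=list)
    self_rating_control_of_self: float | None = None
    flags: SessionFlags = field(default_factory=SessionFlags)

    def __post_init__(self) -> None:
        design = build_phase_design()
        if self.session_index not in design.phase_of_session:
            raise ValidationError(
                f"session_index {self.session_index} outside the 10-session design"
            )
        expected = design.phase_of_session[self.session_index]
        if self.phase != expected:
            raise ValidationError(
                f"phase {self.phase!r} inconsistent with session "
                f"{self.session_index} (design says {expected!r})"
            )
        if self.self_rating_control_of_self is not None and not (
            0 <= self.self_rating_control_of_self <= 100
        ):
            raise ValidationError("self_rating_control_of_self must be in [0, 100]")
        # absent in-game streams are always flagged missing (never silently so)
        if self.ingame_rr is None:
            self.flags.rr_missing = True
        if self.ingame_breathing is None:
            self.flags.breathing_missing = True
        if self.ingame_score is None:
            self.flags.score_missing = True
        for seg in (self.ingame_breathing, self.ingame_rr, self.ingame_score):
            if seg is not None and np.asarray(getattr(seg, "t", getattr(seg, "beat_t", []))).size:
                t0 = getattr(seg, "t", None)
                t0 = (t0 if t0 is not None else seg.beat_t)[0]
                if t0 < self.game_start_t - 1e-9:
                    raise ValidationError("in-game stream starts before game_start_t")


@dataclass(frozen=True)
class PhaseDesign:
    """The fixed ABBABABABA phase map and its consecutive-session contrasts."""

    phase_of_session: Mapping[int, str]
    addition_contrasts: tuple[tuple[int, int], ...]
    removal_contrasts: tuple[tuple[int, int], ...]


def build_phase_design() -> PhaseDesign:
    """Return the ten-session withdrawal design.

    A (no biofeedback): sessions 1, 4, 6, 8, 10.  B (biofeedback): 2, 3, 5,
    7, 9.  Addition contrasts are the A-to-B session pairs, removal contrasts
    the B-to-A pairs; together they cover every consecutive-session phase
    boundary exactly once.
    """
    phases = {s: ("A" if s in (1, 4, 6, 8, 10) else "B") for s in range(1, 11)}
    addition = tuple(
        (i, i + 1) for i in range(1, 10) if phases[i] == "A" and phases[i + 1] == "B"
    )
    removal = tuple(
        (i, i + 1) for i in range(1, 10) if phases[i] == "B" and phases[i + 1] == "A"
    )
    return PhaseDesign(phases, addition, removal)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _stream_to_json(obj):
    if obj is None:
        return None
    if isinstance(obj, BreathingTrace):
        return {"t": obj.t.tolist(), "value": obj.y.tolist(), "rate": obj.rate}
    if isinstance(obj, RRSeries):
        return {"t": obj.beat_t.tolist(), "value": obj.rr.tolist(), "cleaned": obj.cleaned}
    if isinstance(obj, BiofeedbackStream):
        return {"t": obj.t.tolist(), "value": obj.score.tolist()}
    raise TypeError(type(obj))


def _require(d: Mapping, key: str, ctx: str):
    if key not in d:
        raise ValidationError(f"session log: missing field {ctx}.{key}")
    return d[key]


def save_session(record: SessionRecord, path) -> None:
    """Write ``record`` as a canonical JSON session log.

    Keys are sorted and floats use Python's shortest round-trip repr, so two
    saves of the same record are byte-identical and diffs are stable.
    """
    doc = {
        "meta": {
            "subject_id": record.subject_id,
            "session_index": record.session_index,
            "phase": record.phase,
            "game_start_t": record.game_start_t,
            "self_rating_control_of_self": record.self_rating_control_of_self,
            "flags": asdict(record.flags),
        },
        "baseline": {
            "score": _stream_to_json(record.baseline_score),
            "rr": _stream_to_json(record.baseline_rr),
        },
        "ingame": {
            "breathing": _stream_to_json(record.ingame_breathing),
            "rr": _stream_to_json(record.ingame_rr),
            "score": _stream_to_json(record.ingame_score),
            "events": [asdict(e) for e in record.events],
        },
    }
    text = json.dumps(doc, sort_keys=True, indent=1)
    Path(path).write_text(text + "\n")


def load_session(path) -> SessionRecord:
    """Load a JSON session log, validating structure and invariants.

    Streams absent from the file load as ``None`` with the matching flag set;
    they are never imputed.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"session log {path}: not valid JSON ({exc})") from exc
    meta = _require(doc, "meta", "")
    base = _require(doc, "baseline", "")
    ingame = _require(doc, "ingame", "")

    def trace(d):
        if d is None:
            return None
        return BreathingTrace(d["t"], d["value"], d["rate"])

    def rr(d):
        if d is None:
            return None
        return RRSeries(d["t"], d["value"], cleaned=bool(d.get("cleaned", False)))

    def stream(d):
        if d is None:
            return None
        return BiofeedbackStream(d["t"], d["value"])

    flags = SessionFlags(**_require(meta, "flags", "meta"))
    breathing = trace(ingame.get("breathing"))
    ingame_rr = rr(ingame.get("rr"))
    ingame_score = stream(ingame.get("score"))
    if ingame_rr is None:
        flags.rr_missing = True
    if breathing is None:
        flags.breathing_missing = True
    if ingame_score is None:
        flags.score_missing = True
    events = [GameEvent(**e) for e in _require(ingame, "events", "ingame")]
    return SessionRecord(
        subject_id=str(_require(meta, "subject_id", "meta")),
        session_index=int(_require(meta, "session_index", "meta")),
        phase=str(_require(meta, "phase", "meta")),
        game_start_t=float(_require(meta, "game_start_t", "meta")),
        baseline_score=stream(base.get("score")),
        baseline_rr=rr(base.get("rr")),
        ingame_breathing=breathing,
        ingame_rr=ingame_rr,
        ingame_score=ingame_score,
        events=events,
        self_rating_control_of_self=meta.get("self_rating_control_of_self"),
        flags=flags,
    )


def export_streams_csv(record: SessionRecord, outdir) -> list[Path]:
    """Emit one tidy CSV per present stream; returns the written paths."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "baseline_score": record.baseline_score,
        "baseline_rr": record.baseline_rr,
        "ingame_breathing": record.ingame_breathing,
        "ingame_rr": record.ingame_rr,
        "ingame_score": record.ingame_score,
    }
    stem = f"{record.subject_id}_s{record.session_index:02d}"
    for name, obj in tables.items():
        if obj is None:
            continue
        if isinstance(obj, BreathingTrace):
            df = pd.DataFrame({"t": obj.t, "value": obj.y})
        elif isinstance(obj, RRSeries):
            df = pd.DataFrame({"t": obj.beat_t, "value": obj.rr})
        else:
            df = pd.DataFrame({"t": obj.t, "value": obj.score})
        p = outdir / f"{stem}_{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    if record.events:
        df = pd.DataFrame([asdict(e) for e in record.events])
        p = outdir / f"{stem}_events.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written


def write_manifest(rows: Sequence[Mapping], path) -> None:
    """Write a cohort manifest CSV (subject_id, session_index, phase, path)."""
    import pandas as pd

    pd.DataFrame(rows, columns=["subject_id", "session_index", "phase", "path"]).to_csv(
        path, index=False
    )


def read_manifest(path):
    import pandas as pd

    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = {"subject_id", "session_index", "phase", "path"} - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    return df
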