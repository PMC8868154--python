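"""Synthetic ABBABABABA cohort generator with known ground truth.

The restricted training cohort cannot be redistributed, so every pipeline
stage is exercised on simulated subjects whose generative parameters are
known exactly:

* **Breathing** is a phase-continuous chirp — the instantaneous frequency
  (pace/60 Hz) is integrated, never concatenated, so pace changes leave no
  spectral seams — with breath-level pace jitter and an additive
  fixed-amplitude white noise floor.  The noise floor is what makes the
  biofeedback score sensitive to breathing depth.
* **Heart beats** follow an integrate-and-fire (IPFM-style) model of the
  instantaneous heart period: a base period plus respiratory sinus
  arrhythmia (RSA) proportional to the normalized breathing signal, a
  0.1 Hz Mayer-wave term, and slow noise.  Emitting beats by integration
  (rather than perturbing intervals directly) means the tachogram
  interpolation downstream is genuinely exercised.
* **Game events** come from an equal-variance Gaussian observer with true
  sensitivity d' and criterion c, the criterion shifting by a priming bias
  for targets whose body type was announced; the body-type identifier's
  reliability declines linearly from 100% to 50% across the 14 waves.
* **Learning**: each subject's adherence to the rewarded 8 breaths/min pace
  rises with session index, gains a boost while biofeedback is displayed
  (B sessions), and carries a retention fraction of accumulated gains into
  later A sessions.  Adherence mixes the subject's pace between the 8 bpm
  target and a 14 breaths/min unpaced rest rate.

One master seed fixes the whole cohort; every stream is reproducible
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .biofeedback import ScoreParams, score_stream
from .session_model import (
    BODY_TYPES,
    EYE_COLORS,
    BreathingTrace,
    GameEvent,
    RRSeries,
    SessionFlags,
    SessionRecord,
    build_phase_design,
)

__all__ = [
    "LearningParams",
    "BreathingParams",
    "CardiacParams",
    "AgentParams",
    "GameParams",
    "SyntheticCohortConfig",
    "gen_breathing",
    "gen_rr",
    "gen_game_events",
    "gen_session",
    "gen_cohort",
    "adherence_schedule",
]


@dataclass(frozen=True)
class LearningParams:
    """Per-subject pace-adherence dynamics across the ten sessions."""

    base_adherence: float = 0.25   # starting fraction of the way to 8 bpm
    learning_rate: float = 0.05    # accumulated gain per completed session
    bfb_boost: float = 0.30        # extra adherence while biofeedback shown
    transfer_retention: float = 0.60  # fraction of gains kept in A sessions
    subject_sd: float = 0.04       # between-subject spread of base/boost
    max_adherence: float = 0.95


@dataclass(frozen=True)
class BreathingParams:
    depth: float = 1.0             # belt units, sinusoid amplitude
    pace_jitter_sd: float = 1.0    # bpm, breath-to-breath white jitter
    noise_sd: float = 0.25         # belt units, additive white noise floor
    target_pace_bpm: float = 8.0   # rewarded pace
    rest_pace_bpm: float = 14.0    # unpaced breathing rate
    fs: float = 10.0               # sampling rate of the generated trace


@dataclass(frozen=True)
class CardiacParams:
    baseline_hr: float = 75.0      # bpm at rest, before the game
    arousal_delta_hr: float = 10.0  # in-game HR rise over baseline
    rsa_gain_ms: float = 40.0      # heart-period swing per breathing SD
    mayer_amp_ms: float = 15.0     # 0.1 Hz Mayer-wave amplitude
    rr_noise_sd_ms: float = 10.0   # slow (1 s knot) period noise
    mean_hr: float | None = None   # direct override used per segment


@dataclass(frozen=True)
class AgentParams:
    d_prime_true: float = 1.5
    criterion_true: float = 0.30   # conservative: reluctant to shoot
    priming_bias: float = 0.40     # criterion drop for primed targets


@dataclass(frozen=True)
class GameParams:
    n_waves: int = 14
    targets_per_wave: int = 8
    p_hostile: float = 0.5
    reliability_start: float = 1.0  # body-type identifier reliability, wave 1
    reliability_end: float = 0.5    # ... declining linearly to the last wave


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_subjects: int = 9
    session_s: float = 900.0        # ~15 min of gameplay
    baseline_s: float = 60.0        # rest recording before game start
    learning: LearningParams = field(default_factory=LearningParams)
    breathing: BreathingParams = field(default_factory=BreathingParams)
    cardiac: CardiacParams = field(default_factory=CardiacParams)
    agent: AgentParams = field(default_factory=AgentParams)
    game: GameParams = field(default_factory=GameParams)
    score_params: ScoreParams = field(default_factory=ScoreParams)
    include_cardiac: bool = True    # off for score-only simulation studies
    include_events: bool = True
    seed: int = 0

    #: (subject_id, session_index, stream) streams to drop, emulating
    #: equipment failures; stream in {"rr", "breathing"}
    missing: tuple[tuple[str, int, str], ...] = ()


# ---------------------------------------------------------------------------
# signal generators
# ---------------------------------------------------------------------------

def gen_breathing(
    pace_bpm: float | Callable[[np.ndarray], np.ndarray],
    depth: float,
    duration: float,
    seed,
    pace_jitter_sd: float = 0.0,
    noise_sd: float = 0.0,
    fs: float = 10.0,
    t0: float = 0.0,
) -> BreathingTrace:
    """Simulate a respiration-belt trace at a (possibly time-varying) pace.

    The trace is ``depth * sin(phi(t)) + noise`` where ``phi`` integrates the
    instantaneous frequency pace(t)/60 Hz; breath-level pace jitter is drawn
    at one knot per nominal breath and interpolated.  Pace values must stay
    in the physiological 2-40 breaths/min range.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    pace = pace_bpm(t) if callable(pace_bpm) else np.full(n, float(pace_bpm))
    pace = np.asarray(pace, dtype=float)
    if np.any(pace < 2.0) or np.any(pace > 40.0):
        raise ValueError("pace must stay within 2-40 breaths/min")
    if pace_jitter_sd > 0:
        breath_s = 60.0 / float(np.mean(pace))
        knot_t = np.arange(0.0, duration + breath_s, breath_s)
        jitter = rng.normal(0.0, pace_jitter_sd, knot_t.size)
        pace = np.clip(pace + np.interp(t, knot_t, jitter), 2.0, 40.0)
    phase = 2.0 * np.pi * np.cumsum(pace / 60.0) / fs
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    y = depth * np.sin(phase0 + phase)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    return BreathingTrace(t0 + t, y, fs)


def gen_rr(
    breathing: BreathingTrace,
    cardiac: CardiacParams,
    seed,
    mean_hr: float | None = None,
) -> RRSeries:
    """Emit R-peaks by integrate-and-fire over an instantaneous heart period.

    The period (ms) is ``60000/HR + rsa_gain * z(t) + mayer + noise`` with
    ``z`` the unit-variance breathing signal; beats fire whenever the
    integrated instantaneous rate crosses an integer.  The realized mean HR
    lands within ~2% of the target because the modulation terms are small
    relative to the base period.
    """
    hr = mean_hr if mean_hr is not None else (cardiac.mean_hr or cardiac.baseline_hr)
    if not 40.0 <= hr <= 200.0:
        raise ValueError("mean_hr must be within 40-200 bpm")
    rng = np.random.default_rng(seed)
    t = breathing.t - breathing.t[0]
    z = breathing.y - breathing.y.mean()
    sd = z.std()
    z = z / sd if sd > 0 else z
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    h = (
        60000.0 / hr
        + cardiac.rsa_gain_ms * z
        + cardiac.mayer_amp_ms * np.sin(2.0 * np.pi * 0.1 * t + phi0)
    )
    if cardiac.rr_noise_sd_ms > 0:
        knot_t = np.arange(0.0, t[-1] + 1.0, 1.0)
        h = h + np.interp(t, knot_t, rng.normal(0.0, cardiac.rr_noise_sd_ms, knot_t.size))
    if np.min(h) < 300.0:
        raise ValueError("cardiac parameters drive the heart period below 300 ms")
    rate = 1000.0 / h  # beats per second
    # cumulative beat count by trapezoidal integration on the signal grid
    dt = np.diff(t)
    count = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * dt)])
    n_beats = int(np.floor(count[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    idx = np.searchsorted(count, targets)
    frac = (targets - count[idx - 1]) / (count[idx] - count[idx - 1])
    beat_t = t[idx - 1] + frac * (t[idx] - t[idx - 1])
    rr = np.diff(beat_t) * 1000.0
    return RRSeries(breathing.t[0] + beat_t[1:], rr)


def gen_game_events(
    game: GameParams,
    agent: AgentParams,
    duration: float,
    seed,
    game_start_t: float = 0.0,
) -> list[GameEvent]:
    """Simulate one session's shoot/don't-shoot event log.

    Each wave announces a hostile body type (the prime) and a hostile eye
    color.  Hostile targets carry the announced body type with the wave's
    reliability (declining from 100% to 50%), and always the announced eye
    color; friendly targets draw body types uniformly and another eye color.
    The observer shoots when Gaussian evidence (N(d', 1) hostile, N(0, 1)
    friendly) exceeds ``d'/2 + c``, the criterion dropping by
    ``priming_bias`` for targets matching the announced body type.
    """
    rng = np.random.default_rng(seed)
    events: list[GameEvent] = []
    wave_len = duration / game.n_waves
    for wave in range(1, game.n_waves + 1):
        if game.n_waves > 1:
            frac = (wave - 1) / (game.n_waves - 1)
        else:
            frac = 0.0
        reliability = game.reliability_start + frac * (
            game.reliability_end - game.reliability_start
        )
        announced_body = rng.choice(BODY_TYPES)
        hostile_eye = rng.choice(EYE_COLORS)
        other_eyes = [e for e in EYE_COLORS if e != hostile_eye]
        times = game_start_t + wave_len * (wave - 1 + np.sort(rng.random(game.targets_per_wave)))
        for t in times:
            hostile = bool(rng.random() < game.p_hostile)
            if hostile:
                if rng.random() < reliability:
                    body = announced_body
                else:
                    body = rng.choice([b for b in BODY_TYPES if b != announced_body])
                eye = hostile_eye
            else:
                body = rng.choice(BODY_TYPES)
                eye = rng.choice(other_eyes)
            primed = body == announced_body
            evidence = rng.normal(agent.d_prime_true if hostile else 0.0, 1.0)
            threshold = agent.d_prime_true / 2.0 + agent.criterion_true
            if primed:
                threshold -= agent.priming_bias
            shoot = evidence > threshold
            kind = (
                ("shot_hit" if shoot else "miss_reached")
                if hostile
                else ("shot_false_alarm" if shoot else "correct_rejection")
            )
            events.append(
                GameEvent(
                    t=float(t),
                    kind=kind,
                    body_type=str(body),
                    primed=primed,
                    eye_color=str(eye),
                    hostile=hostile,
                    wave=wave,
                    distance=float(rng.uniform(3.0, 30.0)),
                )
            )
    return events


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def adherence_schedule(
    learning: LearningParams, phases: Sequence[str] | None = None
) -> np.ndarray:
    """Pace adherence per session under the learning dynamics.

    Gains accumulate at ``learning_rate`` per completed session; B sessions
    add ``bfb_boost`` on top, while A sessions retain only
    ``transfer_retention`` of the accumulated gains.
    """
    design = build_phase_design()
    phases = phases or [design.phase_of_session[s] for s in range(1, 11)]
    out = np.empty(len(phases))
    for k, ph in enumerate(phases):
        gain = learning.learning_rate * k
        if ph == "B":
            a = learning.base_adherence + gain + learning.bfb_boost
        else:
            a = learning.base_adherence + learning.transfer_retention * gain
        out[k] = min(a, learning.max_adherence)
    return out


def _session_pace(adherence: float, breathing: BreathingParams) -> float:
    return (
        adherence * breathing.target_pace_bpm
        + (1.0 - adherence) * breathing.rest_pace_bpm
    )


def gen_session(
    subject_id: str,
    session_index: int,
    adherence: float,
    config: SyntheticCohortConfig,
    seed_seq: np.random.SeedSequence,
    self_rating: float | None = None,
) -> SessionRecord:
    """Generate one subject-session (baseline + in-game streams + events)."""
    design = build_phase_design()
    phase = design.phase_of_session[session_index]
    br, cd = config.breathing, config.cardiac
    sp = config.score_params
    seeds = seed_seq.spawn(6)
    game_start = sp.window + config.baseline_s

    # belt worn one analysis window before baseline logging starts, so the
    # baseline score stream covers the full rest period
    base_breathing = gen_breathing(
        br.rest_pace_bpm, br.depth, sp.window + config.baseline_s, seeds[0],
        pace_jitter_sd=br.pace_jitter_sd, noise_sd=br.noise_sd, fs=br.fs,
    )
    baseline_score = score_stream(base_breathing, sp)

    ingame_breathing = gen_breathing(
        _session_pace(adherence, br), br.depth, config.session_s, seeds[1],
        pace_jitter_sd=br.pace_jitter_sd, noise_sd=br.noise_sd, fs=br.fs,
        t0=game_start,
    )
    ingame_score = score_stream(ingame_breathing, sp)

    baseline_rr = ingame_rr = None
    if config.include_cardiac:
        base_rest = gen_breathing(
            br.rest_pace_bpm, br.depth, config.baseline_s, seeds[2],
            pace_jitter_sd=br.pace_jitter_sd, noise_sd=br.noise_sd, fs=br.fs,
        )
        baseline_rr = gen_rr(base_rest, cd, seeds[3], mean_hr=cd.baseline_hr)
        ingame_rr = gen_rr(
            ingame_breathing, cd, seeds[4],
            mean_hr=cd.baseline_hr + cd.arousal_delta_hr,
        )

    events: list[GameEvent] = []
    if config.include_events:
        events = gen_game_events(
            config.game, config.agent, config.session_s, seeds[5],
            game_start_t=game_start,
        )

    return SessionRecord(
        subject_id=subject_id,
        session_index=session_index,
        phase=phase,
        game_start_t=game_start,
        baseline_score=baseline_score,
        baseline_rr=baseline_rr,
        ingame_breathing=ingame_breathing,
        ingame_rr=ingame_rr,
        ingame_score=ingame_score,
        events=events,
        self_rating_control_of_self=self_rating,
        flags=SessionFlags(
            rr_missing=ingame_rr is None,
            breathing_missing=False,
            score_missing=False,
        ),
    )


#: self-rating model: early sessions overestimate breathing control, the
#: overestimation decaying geometrically as awareness builds
_OVERESTIMATION_START = 30.0  # percent
_OVERESTIMATION_DECAY = 0.70
_RATING_NOISE_SD = 5.0


def gen_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[SessionRecord], dict]:
    """Generate the full cohort (n_subjects x 10 sessions) plus ground truth.

    Subjects get small seeded perturbations of the learning parameters; the
    returned ground-truth dict records every per-subject adherence schedule
    and the shared agent/cardiac parameters, so recovery tests can compare
    pipeline estimates against the generating values.
    """
    master = np.random.SeedSequence(config.seed)
    subject_seqs = master.spawn(config.n_subjects)
    design = build_phase_design()
    records: list[SessionRecord] = []
    truth_subjects = {}
    missing = set(config.missing)
    for s_idx in range(config.n_subjects):
        subject_id = str(s_idx + 1)
        seq = subject_seqs[s_idx]
        per_subject_rng = np.random.default_rng(seq.spawn(1)[0])
        lp = config.learning
        subject_learning = replace(
            lp,
            base_adherence=float(
                np.clip(lp.base_adherence + per_subject_rng.normal(0, lp.subject_sd), 0.02, 0.9)
            ),
            bfb_boost=float(max(lp.bfb_boost + per_subject_rng.normal(0, lp.subject_sd), 0.0)),
        )
        adherence = adherence_schedule(subject_learning)
        truth_subjects[subject_id] = {
            "adherence": adherence.tolist(),
            "base_adherence": subject_learning.base_adherence,
            "bfb_boost": subject_learning.bfb_boost,
        }
        session_seqs = seq.spawn(10)
        for session_index in range(1, 11):
            overest = _OVERESTIMATION_START * _OVERESTIMATION_DECAY ** (session_index - 1)
            record = gen_session(
                subject_id,
                session_index,
                float(adherence[session_index - 1]),
                config,
                session_seqs[session_index - 1],
            )
            from .behavior import control_of_self  # local import avoids a cycle

            actual = control_of_self(record.ingame_score)
            rating_rng = np.random.default_rng(session_seqs[session_index - 1].spawn(2)[1])
            record.self_rating_control_of_self = float(
                np.clip(actual + overest + rating_rng.normal(0, _RATING_NOISE_SD), 0, 100)
            )
            if (subject_id, session_index, "rr") in missing:
                record.ingame_rr = None
                record.baseline_rr = None
                record.flags.rr_missing = True
            if (subject_id, session_index, "breathing") in missing:
                record.ingame_breathing = None
                record.ingame_score = None
                record.baseline_score = None
                record.flags.breathing_missing = True
                record.flags.score_missing = True
            records.append(record)
    truth = {
        "seed": config.seed,
        "design": {str(s): design.phase_of_session[s] for s in range(1, 11)},
        "subjects": truth_subjects,
        "agent": {
            "d_prime_true": config.agent.d_prime_true,
            "criterion_true": config.agent.criterion_true,
            "priming_bias": config.agent.priming_bias,
        },
        "cardiac": {
            "baseline_hr": config.cardiac.baseline_hr,
            "arousal_delta_hr": config.cardiac.arousal_delta_hr,
            "rsa_gain_ms": config.cardiac.rsa_gain_ms,
        },
    }
    return records, truth
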