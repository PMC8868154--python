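"""YAML configuration for the generator and analysis parameters.

The config file mirrors the nested parameter dataclasses; omitted keys keep
their defaults, so a config listing only ``seed`` and a couple of learning
parameters is valid.
"""

from __future__ import annotations

from dataclasses import fields, is_dataclass, replace
from pathlib import Path

import yaml

from .biofeedback import ScoreParams
from .synthetic import (
    AgentParams,
    BreathingParams,
    CardiacParams,
    GameParams,
    LearningParams,
    SyntheticCohortConfig,
)

__all__ = ["load_cohort_config", "dump_cohort_config"]

_SECTIONS = {
    "learning": LearningParams,
    "breathing": BreathingParams,
    "cardiac": CardiacParams,
    "agent": AgentParams,
    "game": GameParams,
    "score_params": ScoreParams,
}


def _build(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_cohort_config(path) -> SyntheticCohortConfig:
    """Load a cohort config YAML; missing sections/keys use the defaults."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, value in doc.items():
        if key in _SECTIONS:
            kwargs[key] = _build(_SECTIONS[key], value or {})
        elif key == "missing":
            kwargs["missing"] = tuple(
                (str(m["subject_id"]), int(m["session_index"]), str(m["stream"]))
                for m in value
            )
        else:
            kwargs[key] = value
    return _build_top(kwargs)


def _build_top(kwargs: dict) -> SyntheticCohortConfig:
    names = {f.name for f in fields(SyntheticCohortConfig)}
    unknown = set(kwargs) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SyntheticCohortConfig(**kwargs)


def _to_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def dump_cohort_config(config: SyntheticCohortConfig, path) -> None:
    doc = _to_plain(config)
    doc["missing"] = [
        {"subject_id": s, "session_index": i, "stream": st}
        for s, i, st in config.missing
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
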