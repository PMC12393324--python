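"""Table and configuration file formats.

All tables travel as headered CSV (trajectories, detection streams, track
tables, bout tables, stimulus logs); the parameter sets for a whole session
live in one YAML document with ``arena`` / ``behavior`` / ``noise`` /
``tracker`` / ``guard`` / ``trigger`` sections, each mapping directly onto
the corresponding dataclass.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .closed_loop import STIMULUS_COLUMNS, TriggerParams
from .identity_guard import GuardParams
from .kd_tracker import TRACK_COLUMNS, TrackerParams
from .synthetic_arena import (BOUT_COLUMNS, DETECTION_COLUMNS,
                              TRAJECTORY_COLUMNS, ArenaConfig,
                              BehaviorParams, NoiseParams)

__all__ = [
    "SessionConfig",
    "load_config",
    "save_config",
    "read_table",
    "write_table",
]

_SECTIONS = {
    "arena": ArenaConfig,
    "behavior": BehaviorParams,
    "noise": NoiseParams,
    "tracker": TrackerParams,
    "guard": GuardParams,
    "trigger": TriggerParams,
}

_SCHEMAS = {
    "trajectory": TRAJECTORY_COLUMNS,
    "detections": DETECTION_COLUMNS,
    "tracks": TRACK_COLUMNS,
    "bouts": BOUT_COLUMNS,
    "stimulus": STIMULUS_COLUMNS,
}


class SessionConfig:
    """All parameter sets for one session, loaded from a single YAML file."""

    def __init__(self, arena=None, behavior=None, noise=None,
                 tracker=None, guard=None, trigger=None):
        self.arena = arena or ArenaConfig()
        self.behavior = behavior or BehaviorParams()
        self.noise = noise or NoiseParams()
        self.tracker = tracker or TrackerParams()
        self.guard = guard or GuardParams()
        self.trigger = trigger or TriggerParams()

    def to_dict(self) -> dict:
        return {name: asdict(getattr(self, name)) for name in _SECTIONS}


def load_config(path) -> SessionConfig:
    """Read a session YAML; absent sections fall back to defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    unknown = set(doc) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in doc:
            kwargs[name] = cls(**(doc[name] or {}))
    return SessionConfig(**kwargs)


def save_config(config: SessionConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_table(path, kind: str) -> pd.DataFrame:
    """Read one of the pipeline's CSV tables, checking its header."""
    cols = _SCHEMAS[kind]
    df = pd.read_csv(path)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table {path} missing columns: {missing}")
    return df[cols]


def write_table(df: pd.DataFrame, path, kind: str | None = None) -> None:
    if kind is not None:
        missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
        if missing:
            raise ValueError(f"{kind} table missing columns: {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
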