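"""Run configuration: YAML/JSON loading, validation and round-tripping.

A config file is a nested mapping with (all optional) sections
``parameters``, ``solver``, ``schedule``, ``sweep`` and scalar keys
``mode``, ``initial_virus``, ``output_dir``, ``seed``.  Missing keys
fall back to the model defaults; unknown keys are rejected by name so a
typo cannot silently run the wrong simulation.  ``seed`` is accepted
for provenance only — the model is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Any, Optional

import yaml

from .model import ModelParameters
from .radiation import RadiationSchedule
from .solver import SolverSettings

__all__ = ["RunConfig", "SweepSpec", "load_config", "config_to_dict", "save_config"]

_MODES = ("phase1", "two_phase", "sweep")


@dataclass(frozen=True)
class SweepSpec:
    """What to scan: a parameter and/or radiation schedules and timings."""

    parameter: Optional[str] = None
    values: tuple = ()
    timings: tuple = ()
    schedules: tuple = ()  # of mode names, resolved against the schedule section
    mode: str = "phase1"   # phase1 | two_phase

    def __post_init__(self) -> None:
        if self.mode not in ("phase1", "two_phase"):
            raise ValueError(f"sweep mode must be phase1 or two_phase, got {self.mode!r}")
        if self.parameter is not None and not self.values:
            raise ValueError("sweep.values must be nonempty when sweep.parameter is set")


@dataclass(frozen=True)
class RunConfig:
    parameters: ModelParameters = field(default_factory=ModelParameters)
    solver: SolverSettings = field(default_factory=SolverSettings)
    schedule: RadiationSchedule = field(default_factory=RadiationSchedule)
    mode: str = "phase1"
    initial_virus: str = "uniform"
    sweep: SweepSpec = field(default_factory=SweepSpec)
    output_dir: str = "runs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.initial_virus not in ("uniform", "wall"):
            raise ValueError(
                f"initial_virus must be 'uniform' or 'wall', got {self.initial_virus!r}"
            )


def _build(cls, section: dict, name: str):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {name!r} section: {sorted(unknown)}")
    return cls(**section)


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    """Validate a raw mapping and resolve every default."""
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    known = {"parameters", "solver", "schedule", "sweep", "mode",
             "initial_virus", "output_dir", "seed"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    sweep_raw = dict(data.get("sweep") or {})
    for key in ("values", "timings", "schedules"):
        if key in sweep_raw and sweep_raw[key] is not None:
            sweep_raw[key] = tuple(sweep_raw[key])
    return RunConfig(
        parameters=_build(ModelParameters, dict(data.get("parameters") or {}), "parameters"),
        solver=_build(SolverSettings, dict(data.get("solver") or {}), "solver"),
        schedule=_build(RadiationSchedule, dict(data.get("schedule") or {}), "schedule"),
        sweep=_build(SweepSpec, sweep_raw, "sweep"),
        mode=data.get("mode", "phase1"),
        initial_virus=data.get("initial_virus", "uniform"),
        output_dir=data.get("output_dir", "runs"),
        seed=int(data.get("seed", 0)),
    )


def config_to_dict(config: RunConfig) -> dict[str, Any]:
    """Fully-resolved plain mapping; round-trips through config_from_dict."""
    out = asdict(config)
    out["sweep"] = {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in out["sweep"].items()}
    return out


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON — valid YAML) config file with defaults filled in."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ValueError(f"could not parse config {path}: {exc}") from exc
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully-resolved config (YAML) for provenance."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config_to_dict(config), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
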