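"""Run configuration: schema, YAML round-trip, defaults.

A :class:`RunConfig` bundles everything a simulation run needs — scenario,
algorithm, gain table, sensing parameters, batch settings.  Every default
equals the study's printed value where one exists (gain table rows, 0.1 m
success radius, 180 s limit, 10 ms tick, 20 repetitions).  Configs
round-trip losslessly through YAML; unknown keys are rejected by name.

External units follow the robot's conventions (mm/s, rad/s, m, s, Hz).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .agent_sim import DT, SUCCESS_RADIUS, TIME_LIMIT
from .controllers import FsmParams, GainBranch, GainTable
from .core import ConfigurationError
from .environment import (FieldBounds, PlumeConfig, ScenarioConfig,
                          Turbulence, get_scenario)
from .sensing import SensingConfig

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

ALGORITHMS = ("rmi", "szl", "sc")


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of a simulation run."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    algorithm: str = "rmi"
    gains: GainTable = field(default_factory=GainTable)
    fsm: FsmParams = field(default_factory=FsmParams)
    sensing: SensingConfig = field(default_factory=SensingConfig)
    dt: float = DT
    time_limit: float = TIME_LIMIT
    success_radius: float = SUCCESS_RADIUS
    n_trials: int = 20
    seed: int = 0
    out_dir: str = "mothnav_out"

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if self.dt <= 0 or self.time_limit <= 0 or self.success_radius <= 0:
            raise ConfigurationError(
                "dt, time_limit and success_radius must be > 0")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")


_TUPLE_FIELDS = {"odor_source", "wind_source", "start_pose", "mean_wind"}


def _to_dict(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _from_dict(cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ConfigurationError(f"expected a mapping at {path or 'top level'}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        where = f" in {path}" if path else ""
        raise ConfigurationError(
            f"unknown configuration key(s){where}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        sub = _nested_type(f)
        key_path = f"{path}.{name}" if path else name
        if sub is not None and value is not None:
            kwargs[name] = _from_dict(sub, value, key_path)
        elif name in _TUPLE_FIELDS and value is not None:
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    "scenario": ScenarioConfig, "gains": GainTable, "fsm": FsmParams,
    "sensing": SensingConfig, "turbulence": Turbulence, "plume": PlumeConfig,
    "field_bounds": FieldBounds, "active_low": GainBranch,
    "active_high": GainBranch, "inactive_low": GainBranch,
    "inactive_high": GainBranch,
}


def _nested_type(f: dataclasses.Field):
    return _NESTED.get(f.name)


def load_config(path: str | Path | None = None,
                text: str | None = None) -> RunConfig:
    """Load a RunConfig from YAML; absent fields take the study defaults.

    An empty file yields the full default configuration.  Unknown keys are
    rejected with the offending key named.
    """
    if text is None:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    # a bare scenario name is convenient: scenario: b
    if isinstance(data.get("scenario"), str):
        data["scenario"] = _to_dict(get_scenario(data["scenario"]))
    return _from_dict(RunConfig, data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a RunConfig as YAML (load ∘ save is the identity)."""
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the canonical YAML form, for provenance headers."""
    canon = yaml.safe_dump(_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
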