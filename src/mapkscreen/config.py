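"""Run configuration: solver settings, stimulus grid, thresholds, sampling.

Every classification threshold is a config key with the defaults used
throughout: responsiveness O_max > 0.1, significant ultrasensitivity
Gradient > 1.0, bistability index > 1.5, absolute bistability > 9.5,
Gradient anchors at 10% and 90% of the saturated steady-state output.
Unknown keys in a config file are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SolverConfig", "Thresholds", "SamplingConfig", "RunConfig",
    "ConfigError", "default_s_grid",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def default_s_grid(s_max: float = 10.0, n_points: int = 40,
                   s_min: float = 1e-3) -> np.ndarray:
    """{0} followed by ``n_points`` log-spaced stimuli on [s_min, s_max]."""
    return np.concatenate([[0.0], np.geomspace(s_min, s_max, n_points)])


@dataclass(frozen=True)
class SolverConfig:
    """Stiff-integrator and steady-state settings (relative time units)."""

    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    t_cap: float = 2000.0           # cap for the first steady-state stage
    t_cap_slow: float = 50000.0     # extension cap for slow monotone transients
    ss_window: float = 10.0         # window for the state-change criterion
    ss_tol: float = 1e-9            # relative state change per window
    residual_tol: float = 1e-10     # polished steady-state |rhs| bound
    n_output_points: int = 240      # trajectory output grid size

    def tighter(self, factor: float = 10.0) -> "SolverConfig":
        return dataclasses.replace(self, rtol=self.rtol / factor,
                                   atol=self.atol / factor)


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds and Gradient anchors."""

    responsive_o_max: float = 0.1
    ultrasensitive_gradient: float = 1.0
    bistable_index: float = 1.5
    absolute_bistable_index: float = 9.5
    gradient_anchor_low: float = 0.1
    gradient_anchor_high: float = 0.9
    # temporal-dynamics classifier knobs
    oscillation_min_peaks: int = 3
    oscillation_min_amplitude: float = 0.05
    oscillation_persistence: float = 0.5
    transient_decay_fraction: float = 0.5


@dataclass(frozen=True)
class SamplingConfig:
    """Random kinetic-rate sampling: log-uniform on [low, high] per rate."""

    law: str = "log-uniform"
    low: float = 0.1
    high: float = 10.0
    n_rate_vectors: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.law != "log-uniform":
            raise ConfigError(f"unsupported sampling law {self.law!r}")
        if not 0 < self.low < self.high:
            raise ConfigError("sampling range must satisfy 0 < low < high")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration."""

    solver: SolverConfig = field(default_factory=SolverConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    s_max: float = 10.0
    s_grid_points: int = 40
    s_grid_min: float = 1e-3
    screen_s_grid_points: int = 16  # coarser up-branch grid used inside screens
    topologies: tuple[str, ...] = ("none", "positive", "negative")
    max_failure_rate: float = 0.05
    output_dir: str = "mapkscreen_out"

    def s_grid(self) -> np.ndarray:
        return default_s_grid(self.s_max, self.s_grid_points, self.s_grid_min)

    def screen_s_grid(self) -> np.ndarray:
        return default_s_grid(self.s_max, self.screen_s_grid_points, self.s_grid_min)


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown config keys under {path!r}: {sorted(unknown)}")
    return data


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    top = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for name, cls in (("solver", SolverConfig), ("thresholds", Thresholds),
                      ("sampling", SamplingConfig)):
        if name in raw:
            kwargs[name] = cls(**_build(cls, dict(raw[name]), name))
    for name in top - {"solver", "thresholds", "sampling"}:
        if name in raw:
            val = raw[name]
            kwargs[name] = tuple(val) if name == "topologies" else val
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
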