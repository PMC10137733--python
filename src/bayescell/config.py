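"""Scenario configuration: YAML loading, strict validation, defaults.

A scenario bundles a sensing block, sensitivity parameters, the x-grid, an
optional learning block and an optional SDE block.  Unknown keys are
rejected with a message naming the offending key.  The fully populated
default scenario ``fig2-like`` carries the canonical linear-sensing
parameter set b = 2, Xbar = 2, beta' = 0 with g in {0, 1}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import yaml

from .distributions import Grid1D
from .sensing import SensingModel
from .steady_state import SensitivityParams

__all__ = ["ScenarioConfig", "load_config", "default_fig2_config", "parse_sensing_function"]


class ConfigError(ValueError):
    """Raised for missing files, parse errors or schema violations."""


_SENSING_KEYS = {"F", "b", "g", "x_bar", "y_bar", "domain"}
_SENSITIVITY_KEYS = {"beta", "beta_prime", "convention"}
_GRID_KEYS = {"domain", "points"}
_LEARNING_KEYS = {"n_steps", "mode", "seed", "y_domain", "y_points"}
_SDE_KEYS = {"sigma11", "sigma12", "sigma22", "epsilon", "dt", "n_steps", "n_paths", "seed"}
_TOP_KEYS = {"name", "sensing", "sensitivity", "grid", "learning", "sde", "output_dir"}


def parse_sensing_function(spec: str) -> Callable[[float], float]:
    """Parse a sensing-function tag: identity | linear:a,c | hill1:vmax,km."""
    if spec == "identity":
        return lambda x: x
    if spec.startswith("linear:"):
        a, c = (float(v) for v in spec.split(":", 1)[1].split(","))
        return lambda x: a * x + c
    if spec.startswith("hill1:"):
        vmax, km = (float(v) for v in spec.split(":", 1)[1].split(","))
        if km <= 0:
            raise ConfigError("hill1 requires km > 0")
        return lambda x: vmax * x / (km + x)
    raise ConfigError(f"unknown sensing function {spec!r}")


def _check_keys(block: dict, allowed: set, where: str) -> None:
    for key in block:
        if key not in allowed:
            raise ConfigError(
                f"unknown key {key!r} in {where} block (allowed: "
                f"{sorted(allowed)})"
            )


@dataclass
class ScenarioConfig:
    name: str = "scenario"
    sensing: dict = field(default_factory=dict)
    sensitivity: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    learning: dict = field(default_factory=dict)
    sde: Optional[dict] = None
    output_dir: str = "out"

    def __post_init__(self) -> None:
        _check_keys(self.sensing, _SENSING_KEYS, "sensing")
        _check_keys(self.sensitivity, _SENSITIVITY_KEYS, "sensitivity")
        _check_keys(self.grid, _GRID_KEYS, "grid")
        _check_keys(self.learning, _LEARNING_KEYS, "learning")
        if self.sde is not None:
            _check_keys(self.sde, _SDE_KEYS, "sde")
        # defaults
        self.sensing.setdefault("F", "identity")
        self.sensing.setdefault("x_bar", 0.0)
        self.sensing.setdefault("y_bar", 0.0)
        self.sensing.setdefault("domain", [-10.0, 10.0])
        self.sensitivity.setdefault("beta", 1.0)
        self.sensitivity.setdefault("beta_prime", 0.0)
        self.sensitivity.setdefault("convention", "eq29_literal")
        self.grid.setdefault("domain", list(self.sensing["domain"]))
        self.grid.setdefault("points", 2001)
        self.learning.setdefault("n_steps", 10)
        self.learning.setdefault("mode", "observed")
        self.learning.setdefault("seed", 0)
        # validation
        g = self.sensing.get("g")
        if g is not None and g < 0:
            raise ConfigError(f"sensing.g must be >= 0, got {g}")
        b = self.sensing.get("b")
        if b is not None and b <= 0:
            raise ConfigError(f"sensing.b must be > 0, got {b}")
        if self.learning["mode"] not in ("observed", "averaged"):
            raise ConfigError(f"unknown learning.mode {self.learning['mode']!r}")
        if self.grid["points"] < 8:
            raise ConfigError("grid.points must be >= 8")
        lo, hi = self.grid["domain"]
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ConfigError(f"invalid grid.domain {self.grid['domain']!r}")

    # -- builders ----------------------------------------------------------
    def build_sensing_model(self) -> SensingModel:
        blk = self.sensing
        return SensingModel(
            F=parse_sensing_function(blk["F"]),
            b=blk.get("b"),
            g=blk.get("g"),
            x_bar=blk["x_bar"],
            y_bar=blk["y_bar"],
            domain=tuple(blk["domain"]),
        )

    def build_sensitivity(self) -> SensitivityParams:
        blk = self.sensitivity
        return SensitivityParams(
            beta=blk["beta"],
            beta_prime=blk["beta_prime"],
            entropy_convention=blk["convention"],
        )

    def build_grid(self) -> Grid1D:
        lo, hi = self.grid["domain"]
        return Grid1D(lo, hi, int(self.grid["points"]))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "sensing": dict(self.sensing),
            "sensitivity": dict(self.sensitivity),
            "grid": dict(self.grid),
            "learning": dict(self.learning),
            "sde": dict(self.sde) if self.sde else None,
            "output_dir": self.output_dir,
        }


def default_fig2_config(g: float = 0.0) -> ScenarioConfig:
    """Canonical linear-sensing scenario: b = 2, Xbar = 2, beta' = 0."""
    if g not in (0.0, 1.0):
        raise ConfigError("the canonical scenario uses g in {0, 1}")
    domain = [0.0, 33.3] if g == 0 else [0.05, 6.0]
    return ScenarioConfig(
        name=f"fig2-like-g{int(g)}",
        sensing={"F": "identity", "b": 2.0, "g": g, "x_bar": 2.0, "y_bar": 0.0,
                 "domain": domain},
        sensitivity={"beta": 1.0, "beta_prime": 0.0, "convention": "eq29_literal"},
        grid={"domain": list(domain), "points": 2001},
        learning={"n_steps": 10, "mode": "observed", "seed": 0},
    )


def load_config(path) -> ScenarioConfig:
    """Load and validate a YAML scenario configuration."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse {p}: {err}") from err
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    _check_keys(raw, _TOP_KEYS, "top-level")
    return ScenarioConfig(**raw)
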