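"""Structured-text configuration: schema, defaults, validation, round-trip.

The config is a YAML (or JSON) mapping with sections ``pace_functions``,
``range_dynamics``, ``reward``, ``initial_belief``, ``solver``,
``simulation`` and ``beta``.  Unknown keys are rejected and every validation
error names the offending field.  Pace functions accept either explicit
parameters (m, sigma_s, fatigue_shift) or two anchor points
``anchors: [[s_lo, p_lo], [s_hi, p_hi]]`` fed to the two-point calibration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml

from .model import (
    PACE_NAMES,
    DynamicsSpec,
    PaceFunction,
    ParameterError,
    RehabModel,
    RewardSpec,
    default_dynamics,
)

__all__ = ["ConfigError", "RunConfig", "default_config", "load_config", "save_config", "build_model"]


class ConfigError(ValueError):
    """Schema violation; the message names the offending field."""


def default_config() -> dict:
    """The full default configuration as a plain mapping."""
    dyn = default_dynamics()
    return {
        "pace_functions": {
            name: {
                "m": dyn.pace(name).m,
                "sigma_s": dyn.pace(name).sigma_s,
                "fatigue_shift": dyn.pace(name).fatigue_shift,
            }
            for name in PACE_NAMES
        },
        "range_dynamics": {
            "p_up": {
                "lo": {"fresh": 0.4, "fatigued": 0.2},
                "med": {"fresh": 0.7, "fatigued": 0.35},
                "hi": {"fresh": 0.9, "fatigued": 0.45},
            },
            "stretch_up_max": 1,
        },
        "reward": {
            "r_goal": 10.0,
            "r_stretch": 2.0,
            "r_perform": 1.0,
            "c_stop": 3.0,
            "gamma": 0.95,
        },
        "initial_belief": {
            "fatigue_no_prob": 0.95,
            "profile_concentration": 0.85,
        },
        "solver": {
            "belief_points": 500,
            "max_alphas": 60,
            "iterations": 60,
        },
        "simulation": {
            "max_trials": 50,
            "episodes": 1,
        },
        "beta": {
            "u_max": 20.0,
            "grid_step": 0.1,
            "tau": 0.4,
            "kappa": 1.0,
            "fatigue_belief": 0.1,
            "notfat_prior": [6.0, 6.0],
            "fat_prior": [3.5, 8.0],
        },
    }


#: Full-scale solver preset (3,000 belief points, 150 alpha-vectors, 150 stages).
FULL_SCALE_SOLVER = {"belief_points": 3000, "max_alphas": 150, "iterations": 150}


def _require_number(value: Any, path: str, lo: float | None = None, hi: float | None = None) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{path}: expected a number, got {value!r}")
    v = float(value)
    if lo is not None and v < lo:
        raise ConfigError(f"{path}: value {v} below minimum {lo}")
    if hi is not None and v > hi:
        raise ConfigError(f"{path}: value {v} above maximum {hi}")
    return v


def _check_keys(section: Mapping, allowed: set[str], path: str) -> None:
    if not isinstance(section, Mapping):
        raise ConfigError(f"{path}: expected a mapping")
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")


def _merge(base: dict, override: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ConfigError(f"{here}: unknown key")
        if isinstance(base[key], dict):
            if not isinstance(val, Mapping):
                raise ConfigError(f"{here}: expected a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def _merge_pace(defaults: dict, override: Mapping) -> dict:
    """Pace entries may swap parameter style (anchors vs explicit), so they
    replace rather than deep-merge."""
    out = copy.deepcopy(defaults)
    for name, entry in override.items():
        if name not in PACE_NAMES:
            raise ConfigError(f"pace_functions.{name}: unknown pace function")
        out[name] = copy.deepcopy(entry)
    return out


def validate_config(raw: Mapping) -> dict:
    """Fill defaults, reject unknown keys, and bounds-check every field."""
    base = default_config()
    _check_keys(raw, set(base), "config")
    merged = copy.deepcopy(base)
    for key, val in raw.items():
        if key == "pace_functions":
            if not isinstance(val, Mapping):
                raise ConfigError("pace_functions: expected a mapping")
            merged[key] = _merge_pace(base[key], val)
        else:
            merged[key] = _merge(base[key], val, key)

    for name, entry in merged["pace_functions"].items():
        path = f"pace_functions.{name}"
        _check_keys(entry, {"m", "sigma_s", "fatigue_shift", "anchors"}, path)
        if "anchors" in entry:
            anchors = entry["anchors"]
            if (
                not isinstance(anchors, (list, tuple))
                or len(anchors) != 2
                or any(len(a) != 2 for a in anchors)
            ):
                raise ConfigError(f"{path}.anchors: expected [[s, p], [s, p]]")
            for i, (_, p) in enumerate(anchors):
                _require_number(p, f"{path}.anchors[{i}][1]", 0.0, 1.0)
        else:
            _require_number(entry.get("m", 0.0), f"{path}.m")
            if _require_number(entry.get("sigma_s", 0.0), f"{path}.sigma_s") <= 0:
                raise ConfigError(f"{path}.sigma_s: must be positive")
        if "fatigue_shift" in entry:
            _require_number(entry["fatigue_shift"], f"{path}.fatigue_shift")

    rd = merged["range_dynamics"]
    for lr in ("lo", "med", "hi"):
        for cond in ("fresh", "fatigued"):
            _require_number(rd["p_up"][lr][cond], f"range_dynamics.p_up.{lr}.{cond}", 0.0, 1.0)
    _require_number(rd["stretch_up_max"], "range_dynamics.stretch_up_max", 0)

    rw = merged["reward"]
    for key in ("r_goal", "r_stretch", "r_perform", "c_stop"):
        _require_number(rw[key], f"reward.{key}", 0.0)
    g = _require_number(rw["gamma"], "reward.gamma")
    if not (0.0 < g < 1.0):
        raise ConfigError(f"reward.gamma: must lie strictly in (0,1), got {g}")

    ib = merged["initial_belief"]
    _require_number(ib["fatigue_no_prob"], "initial_belief.fatigue_no_prob", 0.0, 1.0)
    _require_number(ib["profile_concentration"], "initial_belief.profile_concentration", 0.0, 1.0)

    sv = merged["solver"]
    for key in ("belief_points", "max_alphas", "iterations"):
        if int(_require_number(sv[key], f"solver.{key}", 1)) != sv[key]:
            raise ConfigError(f"solver.{key}: must be an integer")

    sim = merged["simulation"]
    for key in ("max_trials", "episodes"):
        _require_number(sim[key], f"simulation.{key}", 1)

    bt = merged["beta"]
    _require_number(bt["u_max"], "beta.u_max", 0.0)
    if _require_number(bt["grid_step"], "beta.grid_step") <= 0:
        raise ConfigError("beta.grid_step: must be positive")
    if _require_number(bt["tau"], "beta.tau") <= 0:
        raise ConfigError("beta.tau: must be positive")
    _require_number(bt["kappa"], "beta.kappa", 0.0)
    _require_number(bt["fatigue_belief"], "beta.fatigue_belief", 0.0, 1.0)
    for key in ("notfat_prior", "fat_prior"):
        pr = bt[key]
        if not isinstance(pr, (list, tuple)) or len(pr) != 2:
            raise ConfigError(f"beta.{key}: expected [a, b]")
        for i, v in enumerate(pr):
            if _require_number(v, f"beta.{key}[{i}]") <= 0:
                raise ConfigError(f"beta.{key}[{i}]: must be positive")
    return merged


@dataclass
class RunConfig:
    """Validated configuration plus run-level settings."""

    data: dict = field(default_factory=default_config)

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def model(self) -> RehabModel:
        return build_model(self.data)


def load_config(path_or_mapping: str | Mapping | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config; None gives pure defaults."""
    if path_or_mapping is None:
        raw: Mapping = {}
    elif isinstance(path_or_mapping, Mapping):
        raw = path_or_mapping
    else:
        with open(path_or_mapping) as fh:
            loaded = yaml.safe_load(fh)
        raw = loaded if loaded is not None else {}
        if not isinstance(raw, Mapping):
            raise ConfigError("config root must be a mapping")
    return RunConfig(validate_config(raw))


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.data, fh, sort_keys=True)


def _pace_from_entry(name: str, entry: Mapping) -> PaceFunction:
    shift = float(entry.get("fatigue_shift", 0.0))
    if "anchors" in entry:
        (s_lo, p_lo), (s_hi, p_hi) = entry["anchors"]
        return PaceFunction.from_anchors(
            (float(s_lo), float(p_lo)), (float(s_hi), float(p_hi)), fatigue_shift=shift
        )
    return PaceFunction(
        m=float(entry["m"]), sigma_s=float(entry["sigma_s"]), fatigue_shift=shift
    )


def build_model(cfg: Mapping) -> RehabModel:
    """Instantiate the rehabilitation model from a validated config."""
    paces = {
        name: _pace_from_entry(name, entry)
        for name, entry in cfg["pace_functions"].items()
    }
    rd = cfg["range_dynamics"]
    p_up = np.array(
        [
            [rd["p_up"][lr]["fresh"], rd["p_up"][lr]["fatigued"]]
            for lr in ("lo", "med", "hi")
        ]
    )
    try:
        dyn = DynamicsSpec(
            paces=paces, p_up=p_up, stretch_up_max=int(rd["stretch_up_max"])
        )
        rw = cfg["reward"]
        spec = RewardSpec(
            r_goal=float(rw["r_goal"]),
            r_stretch=float(rw["r_stretch"]),
            r_perform=float(rw["r_perform"]),
            c_stop=float(rw["c_stop"]),
            gamma=float(rw["gamma"]),
        )
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc
    return RehabModel(dynamics=dyn, reward_spec=spec)
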