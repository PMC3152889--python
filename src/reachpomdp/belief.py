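"""Exact Bayes filtering of the hidden patient state.

Beliefs are maintained over the admissible hidden configurations only
(mixed observability): the performance variables are observed exactly, so
the filter's object is a 120-dimensional probability vector over
(fatigue, range profile, learnrate).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .model import (
    ACTION_INDEX,
    LEARNRATES,
    PERF_INDEX,
    Action,
    HiddenState,
    InvariantError,
    ModelError,
    PerformanceState,
    RangeProfile,
    RehabModel,
    admissible_profiles,
    stretch_of,
)

__all__ = [
    "BeliefState",
    "ImpossibleObservationError",
    "update",
    "marginal",
    "initial_belief",
    "rest",
]

_NORM_TOL = 1e-9


class ImpossibleObservationError(ModelError):
    """The observed performance has zero likelihood under the belief."""


@dataclass(frozen=True)
class BeliefState:
    """Probability vector over a model's hidden states."""

    model: RehabModel
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(self.model.hidden_states),):
            raise InvariantError(
                f"belief has {p.shape} entries for "
                f"{len(self.model.hidden_states)} hidden states"
            )
        if (p < -_NORM_TOL).any():
            raise InvariantError("belief contains negative probabilities")
        total = p.sum()
        if not np.isfinite(total) or abs(total - 1.0) > 1e-6:
            raise InvariantError(f"belief sums to {total}, expected 1")
        object.__setattr__(self, "probs", np.maximum(p, 0.0) / p.sum())

    def prob_of(self, hidden: HiddenState) -> float:
        return float(self.probs[self.model.hidden_index[hidden]])

    def as_dict(self) -> dict[str, float]:
        return {
            self.model.state_label(h): float(p)
            for h, p in zip(self.model.hidden_states, self.probs)
            if p > 0.0
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=1, sort_keys=True)


def update(b: BeliefState, action: Action, o: PerformanceState) -> BeliefState:
    """Bayes step: b'(h') proportional to sum_h b(h) P(o, h' | h, action).

    Raises ImpossibleObservationError when the observation has zero
    likelihood (never silently renormalises).
    """
    if action.is_stop:
        raise ModelError("belief update is undefined for the stop action; use rest()")
    ai = ACTION_INDEX[action]
    oi = PERF_INDEX[o]
    kernel = b.model.tabular.joint[ai, :, oi, :]  # (H, H')
    post = b.probs @ kernel
    total = post.sum()
    if total <= 0.0:
        raise ImpossibleObservationError(
            f"observation {o} has zero likelihood after action {action.label()}"
        )
    return BeliefState(b.model, post / total)


def rest(b: BeliefState) -> BeliefState:
    """Episode-boundary transform: fatigue resets to no, ranges carry over."""
    model = b.model
    post = np.zeros_like(b.probs)
    for h, p in zip(model.hidden_states, b.probs):
        if p <= 0.0:
            continue
        h2 = HiddenState(False, h.ranges, h.learnrate)
        post[model.hidden_index[h2]] += p
    return BeliefState(model, post)


def marginal(
    b: BeliefState, variable: str, action: Action | None = None
) -> dict:
    """Marginal distribution of one hidden variable.

    ``variable`` is one of fatigue, n_none, n_min, n_max, learnrate, or
    stretch (which requires ``action`` and is the push-forward of the range
    marginal through the stretch function).
    """
    model = b.model
    if variable == "fatigue":
        out = {"no": 0.0, "yes": 0.0}
        for h, p in zip(model.hidden_states, b.probs):
            out["yes" if h.fatigued else "no"] += float(p)
        return out
    if variable in ("n_none", "n_min", "n_max"):
        idx = ("n_none", "n_min", "n_max").index(variable)
        out = {lvl: 0.0 for lvl in ("none", "d1", "d2", "d3")}
        for h, p in zip(model.hidden_states, b.probs):
            out[h.ranges.labels()[idx]] += float(p)
        return out
    if variable == "learnrate":
        out = {lvl: 0.0 for lvl in LEARNRATES}
        for h, p in zip(model.hidden_states, b.probs):
            out[LEARNRATES[h.learnrate]] += float(p)
        return out
    if variable == "stretch":
        if action is None or action.is_stop:
            raise ModelError("stretch marginal needs a set-target action")
        out_s: dict[int, float] = {}
        for h, p in zip(model.hidden_states, b.probs):
            if p <= 0.0:
                continue
            s = stretch_of(action, h.ranges)
            out_s[s] = out_s.get(s, 0.0) + float(p)
        return out_s
    raise ModelError(f"unknown variable {variable!r}")


def initial_belief(
    model: RehabModel,
    profile_prior: str | RangeProfile | dict,
    fatigue_no_prob: float = 0.95,
    profile_concentration: float = 0.85,
    decay: float = 1.0,
) -> BeliefState:
    """Initial belief for one of the 20 admissible range possibilities.

    Fatigue starts at no with probability ``fatigue_no_prob`` (0.95 by
    default), learnrate is uniform, and the range marginal puts
    ``profile_concentration`` of its mass on the named profile with the
    remainder spread *locally*: each other admissible profile gets weight
    exp(-d / decay), d being its L1 distance from the named profile, so
    pre-assessment uncertainty sits on adjacent ability levels rather than
    on the far end of the ladder.  An explicit dict {HiddenState: weight}
    is normalised and passed through.
    """
    if isinstance(profile_prior, dict):
        probs = np.zeros(len(model.hidden_states))
        for h, w in profile_prior.items():
            probs[model.hidden_index[h]] = float(w)
        if probs.sum() <= 0:
            raise ModelError("explicit belief map has zero total mass")
        return BeliefState(model, probs / probs.sum())

    profiles = admissible_profiles()
    if isinstance(profile_prior, str):
        named = _parse_profile(profile_prior)
    else:
        named = RangeProfile(*profile_prior)
    if named not in profiles:
        raise ModelError(f"unknown/inadmissible profile {profile_prior!r}")
    others = [p for p in profiles if p != named]
    weights = np.array(
        [math.exp(-sum(abs(a - b) for a, b in zip(p, named)) / decay) for p in others]
    )
    weights *= (1.0 - profile_concentration) / weights.sum()
    range_mass = {named: profile_concentration}
    range_mass.update(zip(others, weights))
    probs = np.empty(len(model.hidden_states))
    for i, h in enumerate(model.hidden_states):
        p_f = (1.0 - fatigue_no_prob) if h.fatigued else fatigue_no_prob
        probs[i] = p_f * range_mass[h.ranges] / 3.0
    return BeliefState(model, probs)


def _parse_profile(name: str) -> RangeProfile:
    """Parse 'd3/d3/d1' or 'none/none/none' style profile names."""
    levels = ("none", "d1", "d2", "d3")
    parts = name.replace(",", "/").split("/")
    if len(parts) != 3 or any(p.strip() not in levels for p in parts):
        raise ModelError(f"cannot parse profile name {name!r}")
    return RangeProfile(*(levels.index(p.strip()) for p in parts))


def all_initial_beliefs(
    model: RehabModel,
    fatigue_no_prob: float = 0.95,
    profile_concentration: float = 0.85,
) -> list[BeliefState]:
    """One initial belief per admissible range possibility (20 in all)."""
    return [
        initial_belief(model, prof, fatigue_no_prob, profile_concentration)
        for prof in admissible_profiles()
    ]
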