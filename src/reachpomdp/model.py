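"""Factored POMDP model of an adaptive upper-limb reaching exercise.

The controller chooses a target distance (``d1 < d2 < d3``) and a resistance
level (``none < min < max``) for each reaching trial, or stops the exercise so
the patient can rest.  The patient's condition is hidden: whether they are
fatigued, their *range* (furthest distance reachable) at each resistance
level, and a static learning-rate trait.  After each trial the system
observes the performance — time-to-target (``ttt``), control (``ctrl``) and
trunk compensation (``comp``) — and must infer the hidden condition from it.

The model is *mixed-observability*: the performance variables are observed
exactly, so beliefs only need to range over the hidden
(fatigue, ranges, learnrate) configurations (120 admissible states once the
range-monotonicity constraint is enforced).  The flat product space that also
mirrors performance and stretch in the state (82,944 joint values with the
monotonicity constraint relaxed) is retained purely as an enumeration view.

Dynamics are driven by the *stretch* of an action — how far the commanded
target sits beyond the patient's current ability ladder — through sigmoid
*pace functions* that map (stretch, fatigue) to outcome probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "RESISTANCES",
    "DISTANCES",
    "RANGE_LEVELS",
    "TTT_LEVELS",
    "CTRL_LEVELS",
    "LEARNRATES",
    "PACE_NAMES",
    "ModelError",
    "InvariantError",
    "UndefinedStretchError",
    "ParameterError",
    "CalibrationError",
    "Action",
    "ACTIONS",
    "STOP",
    "RangeProfile",
    "HiddenState",
    "PerformanceState",
    "PERF_STATES",
    "PERF_INDEX",
    "REST_PERF",
    "FullState",
    "PaceFunction",
    "DynamicsSpec",
    "RewardSpec",
    "RehabModel",
    "TabularPOMDP",
    "stretch_of",
    "admissible_profiles",
    "STRETCH_MIN",
    "STRETCH_MAX",
    "STRETCH_VALUES",
]

# ---------------------------------------------------------------------------
# Variable alphabets (1-based resistance/distance indices match clinical use)
# ---------------------------------------------------------------------------

RESISTANCES = ("none", "min", "max")  # resistance level r = 1, 2, 3
DISTANCES = ("d1", "d2", "d3")  # target distance a_d = 1, 2, 3
RANGE_LEVELS = ("none", "d1", "d2", "d3")  # range index n_r = 0..3
TTT_LEVELS = ("none", "slow", "norm")
CTRL_LEVELS = ("none", "min", "max")
LEARNRATES = ("lo", "med", "hi")

#: Names of the per-outcome pace functions.  Each gives the probability of the
#: *adverse* binary event so that every curve is increasing in stretch:
#:   fail       P(ttt = none)                -- failed to reach the target
#:   slow       P(ttt = slow | reached)
#:   ctrl_none  P(ctrl = none)
#:   ctrl_min   P(ctrl = min | ctrl != none)
#:   comp       P(comp = yes)
#:   fatigue    P(fatigue yes at t+1 | fatigue no at t)  -- onset hazard
PACE_NAMES = ("fail", "slow", "ctrl_none", "ctrl_min", "comp", "fatigue")

STRETCH_MIN = -2
STRETCH_MAX = 9
STRETCH_VALUES = tuple(range(STRETCH_MIN, STRETCH_MAX + 1))  # 12 values


class ModelError(Exception):
    """Base class for model-definition errors."""


class InvariantError(ModelError):
    """A structural invariant (e.g. range monotonicity) is violated."""


class UndefinedStretchError(ModelError):
    """Stretch requested for the stop action, which sets no target."""


class ParameterError(ModelError):
    """A pace-function or dynamics parameter is out of its valid domain."""


class CalibrationError(ParameterError):
    """Two-point pace calibration given non-monotone anchors."""


# ---------------------------------------------------------------------------
# Actions
# ---------------------------------------------------------------------------


class Action(NamedTuple):
    """A controller decision: set a (distance, resistance) target, or stop.

    ``a_d`` and ``a_r`` are the 1-based distance / resistance indices; both
    are 0 for the stop action.
    """

    kind: str  # "set_target" | "stop"
    a_d: int = 0
    a_r: int = 0

    @property
    def is_stop(self) -> bool:
        return self.kind == "stop"

    def label(self) -> str:
        if self.is_stop:
            return "stop"
        return f"{DISTANCES[self.a_d - 1]}@{RESISTANCES[self.a_r - 1]}"


def _enumerate_actions() -> tuple[Action, ...]:
    acts = [
        Action("set_target", a_d, a_r)
        for a_r in (1, 2, 3)
        for a_d in (1, 2, 3)
    ]
    acts.append(Action("stop"))
    return tuple(acts)


#: The 10 actions, ordered by (resistance, distance) with stop last.  All
#: deterministic tie-breaks resolve to the lowest index in this list.
ACTIONS: tuple[Action, ...] = _enumerate_actions()
STOP: Action = ACTIONS[-1]
ACTION_INDEX: dict[Action, int] = {a: i for i, a in enumerate(ACTIONS)}


def make_action(distance: int | str, resistance: int | str) -> Action:
    """Convenience constructor accepting labels ('d3', 'max') or indices."""
    a_d = DISTANCES.index(distance) + 1 if isinstance(distance, str) else int(distance)
    a_r = (
        RESISTANCES.index(resistance) + 1
        if isinstance(resistance, str)
        else int(resistance)
    )
    if not (1 <= a_d <= 3 and 1 <= a_r <= 3):
        raise ModelError(f"invalid target indices ({a_d}, {a_r})")
    return Action("set_target", a_d, a_r)


# ---------------------------------------------------------------------------
# Range profiles and stretch
# ---------------------------------------------------------------------------


class RangeProfile(NamedTuple):
    """Range index n_r in 0..3 at each resistance (0 = no reach at all)."""

    n_none: int
    n_min: int
    n_max: int

    @property
    def admissible(self) -> bool:
        """Monotonicity: range can never be larger at a higher resistance."""
        return 3 >= self.n_none >= self.n_min >= self.n_max >= 0

    def ladder(self) -> int:
        """Best attained ladder position 3(r-1) + n_r over resistances.

        A resistance with no range (n_r = 0) contributes nothing; the empty
        profile has ladder position 0.
        """
        best = 0
        for r, n in enumerate(self, start=1):
            if n > 0:
                best = max(best, 3 * (r - 1) + n)
        return best

    def labels(self) -> tuple[str, str, str]:
        return tuple(RANGE_LEVELS[n] for n in self)  # type: ignore[return-value]


def admissible_profiles() -> tuple[RangeProfile, ...]:
    """The 20 monotone range profiles, in lexicographic order."""
    return tuple(
        RangeProfile(a, b, c)
        for a in range(4)
        for b in range(a + 1)
        for c in range(b + 1)
    )


def stretch_of(action: Action, ranges: RangeProfile) -> int:
    """Integer stretch of a set-target action against the current ranges.

    The commanded (distance, resistance) pair occupies ladder position
    3(a_r - 1) + a_d; the stretch is that position minus the patient's best
    attained ladder position, floored at the domain minimum -2.
    """
    if action.is_stop:
        raise UndefinedStretchError("stretch is undefined for the stop action")
    if not isinstance(ranges, RangeProfile):
        ranges = RangeProfile(*ranges)
    if not ranges.admissible:
        raise InvariantError(f"inadmissible range profile {ranges}")
    raw = (3 * (action.a_r - 1) + action.a_d) - ranges.ladder()
    return max(STRETCH_MIN, raw)


# ---------------------------------------------------------------------------
# States
# ---------------------------------------------------------------------------


class HiddenState(NamedTuple):
    """Unobservable patient condition: fatigue, ranges, learning rate."""

    fatigued: bool
    ranges: RangeProfile
    learnrate: int  # 0 = lo, 1 = med, 2 = hi


class PerformanceState(NamedTuple):
    """Observed trial outcome."""

    ttt: str  # none | slow | norm
    ctrl: str  # none | min | max
    comp: bool


PERF_STATES: tuple[PerformanceState, ...] = tuple(
    PerformanceState(ttt, ctrl, comp)
    for ttt in TTT_LEVELS
    for ctrl in CTRL_LEVELS
    for comp in (False, True)
)
PERF_INDEX: dict[PerformanceState, int] = {p: i for i, p in enumerate(PERF_STATES)}

#: Conventional observation emitted by the stop action (nothing happened).
REST_PERF = PerformanceState("none", "none", False)


class FullState(NamedTuple):
    """Flat joint state mirroring the previous trial's performance/stretch."""

    hidden: HiddenState
    perf: PerformanceState
    stretch: int


def enumerate_full_states(relaxed: bool = True) -> Iterator[FullState]:
    """Enumerate the flat joint state space.

    With ``relaxed=True`` the range-monotonicity constraint is dropped and
    stretch runs over all 12 domain values, yielding the
    2 * 4^3 * 12 * 3 * 3 * 3 * 2 = 82,944 joint configurations.
    """
    profiles: Sequence[RangeProfile]
    if relaxed:
        profiles = [
            RangeProfile(a, b, c)
            for a in range(4)
            for b in range(4)
            for c in range(4)
        ]
    else:
        profiles = admissible_profiles()
    for fatigued in (False, True):
        for prof in profiles:
            for s in STRETCH_VALUES:
                for lr in range(3):
                    for perf in PERF_STATES:
                        yield FullState(HiddenState(fatigued, prof, lr), perf, s)


# ---------------------------------------------------------------------------
# Pace functions
# ---------------------------------------------------------------------------


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class PaceFunction:
    """Sigmoid pace function phi(s, f) = sigmoid((s - m - m(f)) / sigma_s).

    ``m`` is the mean stretch (phi = 0.5 at s = m when not fatigued),
    ``sigma_s`` the slope scale, and ``fatigue_shift`` the horizontal shift
    m(f) applied when the patient is fatigued (0 otherwise).  A *negative*
    shift moves the curve left, making the modelled (adverse) event more
    probable at equal stretch.
    """

    m: float
    sigma_s: float
    fatigue_shift: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma_s > 0):
            raise ParameterError(f"sigma_s must be positive, got {self.sigma_s}")

    def __call__(self, s: float, fatigued: bool = False) -> float:
        shift = self.fatigue_shift if fatigued else 0.0
        z = (s - self.m - shift) / self.sigma_s
        # math.exp under/overflow guard; output stays strictly inside (0, 1)
        if z >= 0:
            return 1.0 / (1.0 + math.exp(-z))
        e = math.exp(z)
        return e / (1.0 + e)

    def shifted(self, delta_m: float) -> "PaceFunction":
        """Horizontally shifted copy (positive delta lowers the probability)."""
        return replace(self, m=self.m + delta_m)

    @classmethod
    def from_anchors(
        cls,
        limit_lo: tuple[float, float],
        limit_hi: tuple[float, float],
        fatigue_shift: float = 0.0,
    ) -> "PaceFunction":
        """Two-point calibration from (stretch, probability) pace limits.

        Solves the logistic exactly so both anchors are reproduced:
        sigma_s = (s_hi - s_lo) / (logit(p_hi) - logit(p_lo)),
        m = s_lo - sigma_s * logit(p_lo).
        """
        s_lo, p_lo = limit_lo
        s_hi, p_hi = limit_hi
        if not (0.0 < p_lo < 1.0 and 0.0 < p_hi < 1.0):
            raise CalibrationError("anchor probabilities must lie strictly in (0,1)")
        if not (s_lo < s_hi and p_lo < p_hi):
            raise CalibrationError(
                f"anchors must be increasing: ({s_lo},{p_lo}) -> ({s_hi},{p_hi})"
            )
        sigma = (s_hi - s_lo) / (_logit(p_hi) - _logit(p_lo))
        m = s_lo - sigma * _logit(p_lo)
        return cls(m=m, sigma_s=sigma, fatigue_shift=fatigue_shift)


#: Alias matching the operation name used throughout the docs.
def calibrate_pace(
    limit_lo: tuple[float, float],
    limit_hi: tuple[float, float],
    fatigue_shift: float = 0.0,
) -> PaceFunction:
    return PaceFunction.from_anchors(limit_lo, limit_hi, fatigue_shift)


def pace_value(p: PaceFunction, s: float, fatigued: bool = False) -> float:
    return p(s, fatigued)


# ---------------------------------------------------------------------------
# Dynamics and reward specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DynamicsSpec:
    """Per-outcome pace functions plus the range-growth model.

    ``p_up[learnrate][fatigued]`` is the probability that a successful trial
    at stretch 0..stretch_up_max grows the practised range by one step.
    Growth must be faster for higher learning rates and slower when fatigued.
    """

    paces: Mapping[str, PaceFunction]
    p_up: np.ndarray = field(
        default_factory=lambda: np.array([[0.4, 0.2], [0.7, 0.35], [0.9, 0.45]])
    )
    stretch_up_max: int = 1

    def __post_init__(self) -> None:
        missing = set(PACE_NAMES) - set(self.paces)
        if missing:
            raise ParameterError(f"missing pace functions: {sorted(missing)}")
        p = np.asarray(self.p_up, dtype=float)
        if p.shape != (3, 2):
            raise ParameterError("p_up must be a 3 (learnrate) x 2 (fatigue) table")
        if (p < 0).any() or (p > 1).any():
            raise ParameterError("p_up entries must be probabilities")
        if not (np.diff(p, axis=0) >= -1e-12).all():
            raise ParameterError("p_up must be non-decreasing in learnrate")
        if not (p[:, 1] <= p[:, 0] + 1e-12).all():
            raise ParameterError("p_up must not be larger when fatigued")
        object.__setattr__(self, "p_up", p)

    def pace(self, name: str) -> PaceFunction:
        return self.paces[name]


@dataclass(frozen=True)
class RewardSpec:
    """Reward weights.

    r_goal is earned when the patient *reaches* the furthest target (d3) at
    maximum resistance; r_stretch when the commanded target is at or beyond
    the current range (stretch >= 0); r_perform for a clean trial
    (ttt=norm, ctrl=max, comp=no).  No reward at all is given when the
    patient is fatigued, fails to reach, has no control, or compensates.
    The stop action costs c_stop.  gamma is the discount factor.
    """

    r_goal: float = 10.0
    r_stretch: float = 2.0
    r_perform: float = 1.0
    c_stop: float = 3.0
    gamma: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 1.0):
            raise ParameterError(f"gamma must lie in (0,1), got {self.gamma}")
        if self.r_goal < 0 or self.r_stretch < 0 or self.r_perform < 0:
            raise ParameterError("reward weights must be non-negative")
        if self.r_goal and self.r_goal <= max(self.r_stretch, self.r_perform):
            raise ParameterError("r_goal must dominate the smaller rewards")


def default_dynamics() -> DynamicsSpec:
    """Default calibration.

    The compensation pace reproduces the example pace limits: probability
    0.10 at stretch -1 and 0.90 at stretch +3 when not fatigued.  The other
    curves are chosen so that trials at or just above range usually succeed
    cleanly, outcomes degrade with stretch, fatigue makes every adverse
    outcome more likely at equal stretch (negative shifts), and the fatigue
    onset hazard at low stretch makes the filtered fatigue probability climb
    from ~5% to ~20% over roughly six clean repetitions.
    """
    paces = {
        "fail": PaceFunction.from_anchors((0, 0.10), (4, 0.90), fatigue_shift=-0.25),
        "slow": PaceFunction.from_anchors((0, 0.15), (4, 0.85), fatigue_shift=-0.25),
        "ctrl_none": PaceFunction.from_anchors((1, 0.05), (6, 0.80), fatigue_shift=-0.25),
        "ctrl_min": PaceFunction.from_anchors((0, 0.20), (4, 0.80), fatigue_shift=-0.25),
        "comp": PaceFunction.from_anchors((-1, 0.10), (3, 0.90), fatigue_shift=-1.0),
        "fatigue": PaceFunction(m=6.0, sigma_s=2.2),
    }
    return DynamicsSpec(paces=paces)


# ---------------------------------------------------------------------------
# Tabular mixed-observability POMDP (generic container used by the solver)
# ---------------------------------------------------------------------------


@dataclass
class TabularPOMDP:
    """Enumerated discrete POMDP over a hidden state space.

    ``joint[a][h, o, h']`` = P(o, h' | h, a): the joint probability of
    emitting observation o and moving to hidden state h' when action a is
    taken in hidden state h.  ``rho[a][h]`` is the expected immediate reward
    of action a in hidden state h.  This is everything the Bayes filter and
    the point-based solver need.
    """

    joint: np.ndarray  # (A, H, O, H)
    rho: np.ndarray  # (A, H)
    gamma: float
    action_labels: Sequence[str] = ()
    state_labels: Sequence[str] = ()
    obs_labels: Sequence[str] = ()

    @property
    def n_actions(self) -> int:
        return self.joint.shape[0]

    @property
    def n_states(self) -> int:
        return self.joint.shape[1]

    @property
    def n_obs(self) -> int:
        return self.joint.shape[2]

    def validate(self, tol: float = 1e-9) -> None:
        sums = self.joint.sum(axis=(2, 3))
        if not np.allclose(sums, 1.0, atol=tol):
            raise InvariantError("joint transition rows must sum to 1")
        if (self.joint < -tol).any():
            raise InvariantError("negative transition probability")


# ---------------------------------------------------------------------------
# The rehabilitation model proper
# ---------------------------------------------------------------------------


class RehabModel:
    """Enumerable factored model tying dynamics and reward together.

    Hidden states are the admissible (fatigue, ranges, learnrate)
    configurations; performance is observed.  The stop action is modelled as
    a one-step rest: fatigue resets to no, ranges and learnrate carry over,
    and the conventional REST_PERF observation is emitted.
    """

    def __init__(
        self,
        dynamics: DynamicsSpec | None = None,
        reward_spec: RewardSpec | None = None,
    ) -> None:
        self.dynamics = dynamics if dynamics is not None else default_dynamics()
        self.reward_spec = reward_spec if reward_spec is not None else RewardSpec()
        self.profiles = admissible_profiles()
        self.hidden_states: tuple[HiddenState, ...] = tuple(
            HiddenState(f, prof, lr)
            for f in (False, True)
            for prof in self.profiles
            for lr in range(3)
        )
        self.hidden_index: dict[HiddenState, int] = {
            h: i for i, h in enumerate(self.hidden_states)
        }

    # -- local conditional distributions ----------------------------------

    def transition_performance(
        self, hidden: HiddenState, action: Action
    ) -> np.ndarray:
        """P(perf | hidden, set-target action) over the 18 PERF_STATES."""
        s = stretch_of(action, hidden.ranges)
        f = hidden.fatigued
        dyn = self.dynamics
        p_fail = dyn.pace("fail")(s, f)
        p_slow = dyn.pace("slow")(s, f)
        p_cn = dyn.pace("ctrl_none")(s, f)
        p_cm = dyn.pace("ctrl_min")(s, f)
        p_comp = dyn.pace("comp")(s, f)
        p_ttt = {
            "none": p_fail,
            "slow": (1 - p_fail) * p_slow,
            "norm": (1 - p_fail) * (1 - p_slow),
        }
        p_ctrl = {
            "none": p_cn,
            "min": (1 - p_cn) * p_cm,
            "max": (1 - p_cn) * (1 - p_cm),
        }
        out = np.empty(len(PERF_STATES))
        for i, perf in enumerate(PERF_STATES):
            out[i] = (
                p_ttt[perf.ttt]
                * p_ctrl[perf.ctrl]
                * (p_comp if perf.comp else 1 - p_comp)
            )
        return out

    def transition_fatigue(
        self, hidden: HiddenState, action: Action, stretch: int
    ) -> float:
        """P(fatigued at t+1).  Fatigue is sticky within an episode."""
        if hidden.fatigued:
            return 1.0
        if action.is_stop:
            return 0.0
        return self.dynamics.pace("fatigue")(stretch, False)

    def transition_ranges(
        self, hidden: HiddenState, action: Action, perf: PerformanceState
    ) -> dict[RangeProfile, float]:
        """Range-growth kernel given the trial's observed performance.

        Practising successfully (ttt != none) at a stretch between 0 and
        stretch_up_max grows the range at the commanded resistance by one
        step with probability p_up(learnrate, fatigue).  A range already at
        d3 spills over: the next resistance's range moves none -> d1.  Any
        growth that would break monotonicity is suppressed.
        """
        prof = hidden.ranges
        if not prof.admissible:
            raise InvariantError(f"inadmissible range profile {prof}")
        if action.is_stop:
            return {prof: 1.0}
        s = stretch_of(action, prof)
        success = perf.ttt != "none"
        if not success or not (0 <= s <= self.dynamics.stretch_up_max):
            return {prof: 1.0}
        grown = self._grow(prof, action.a_r)
        if grown is None:
            return {prof: 1.0}
        p = float(self.dynamics.p_up[hidden.learnrate, int(hidden.fatigued)])
        if p <= 0.0:
            return {prof: 1.0}
        if p >= 1.0:
            return {grown: 1.0}
        return {prof: 1.0 - p, grown: p}

    @staticmethod
    def _grow(prof: RangeProfile, a_r: int) -> RangeProfile | None:
        levels = list(prof)
        i = a_r - 1
        if levels[i] == 3:
            # spill over to the next higher resistance, none -> d1 only
            if i < 2 and levels[i + 1] == 0:
                levels[i + 1] = 1
            else:
                return None
        else:
            levels[i] += 1
        cand = RangeProfile(*levels)
        return cand if cand.admissible else None

    # -- reward ------------------------------------------------------------

    def reward(
        self, hidden: HiddenState, action: Action, perf: PerformanceState
    ) -> float:
        """Per-trial reward; see RewardSpec for the gating rules."""
        rs = self.reward_spec
        if action.is_stop:
            return -rs.c_stop
        if hidden.fatigued:
            return 0.0
        if perf.ttt == "none" or perf.ctrl == "none" or perf.comp:
            return 0.0
        r = 0.0
        if stretch_of(action, hidden.ranges) >= 0:
            r += rs.r_stretch
        if perf.ttt == "norm" and perf.ctrl == "max" and not perf.comp:
            r += rs.r_perform
        if action.a_d == 3 and action.a_r == 3:
            r += rs.r_goal
        return r

    # -- joint transitions -------------------------------------------------

    def hidden_step(
        self, hidden: HiddenState, action: Action
    ) -> dict[tuple[int, HiddenState], float]:
        """Joint P(obs index, next hidden | hidden, action)."""
        out: dict[tuple[int, HiddenState], float] = {}
        if action.is_stop:
            nxt = HiddenState(False, hidden.ranges, hidden.learnrate)
            out[(PERF_INDEX[REST_PERF], nxt)] = 1.0
            return out
        s = stretch_of(action, hidden.ranges)
        p_perf = self.transition_performance(hidden, action)
        p_fat = self.transition_fatigue(hidden, action, s)
        for o_idx, perf in enumerate(PERF_STATES):
            po = p_perf[o_idx]
            if po <= 0.0:
                continue
            ranges_dist = self.transition_ranges(hidden, action, perf)
            for f_next, pf in ((True, p_fat), (False, 1.0 - p_fat)):
                if pf <= 0.0:
                    continue
                for prof, pr in ranges_dist.items():
                    h_next = HiddenState(f_next, prof, hidden.learnrate)
                    key = (o_idx, h_next)
                    out[key] = out.get(key, 0.0) + po * pf * pr
        return out

    def transition(self, full: FullState, action: Action) -> dict[FullState, float]:
        """Joint next-state distribution on the flat state view."""
        hidden = full.hidden
        out: dict[FullState, float] = {}
        if action.is_stop:
            nxt = FullState(
                HiddenState(False, hidden.ranges, hidden.learnrate),
                REST_PERF,
                full.stretch,
            )
            return {nxt: 1.0}
        s = stretch_of(action, hidden.ranges)
        for (o_idx, h_next), p in self.hidden_step(hidden, action).items():
            fs = FullState(h_next, PERF_STATES[o_idx], s)
            out[fs] = out.get(fs, 0.0) + p
        return out

    @staticmethod
    def observation_prob(
        o: PerformanceState, action: Action, next_full: FullState
    ) -> float:
        """Mixed observability: the observation is the next performance."""
        return 1.0 if o == next_full.perf else 0.0

    # -- enumerated arrays --------------------------------------------------

    @cached_property
    def tabular(self) -> TabularPOMDP:
        """Dense (A, H, O, H) joint kernel and (A, H) expected rewards."""
        H = len(self.hidden_states)
        A = len(ACTIONS)
        O = len(PERF_STATES)
        joint = np.zeros((A, H, O, H))
        rho = np.zeros((A, H))
        for ai, action in enumerate(ACTIONS):
            for hi, hidden in enumerate(self.hidden_states):
                for (o_idx, h_next), p in self.hidden_step(hidden, action).items():
                    joint[ai, hi, o_idx, self.hidden_index[h_next]] += p
                if action.is_stop:
                    rho[ai, hi] = -self.reward_spec.c_stop
                else:
                    p_perf = self.transition_performance(hidden, action)
                    rho[ai, hi] = sum(
                        p_perf[oi] * self.reward(hidden, action, perf)
                        for oi, perf in enumerate(PERF_STATES)
                        if p_perf[oi] > 0.0
                    )
        tab = TabularPOMDP(
            joint=joint,
            rho=rho,
            gamma=self.reward_spec.gamma,
            action_labels=[a.label() for a in ACTIONS],
            state_labels=[self.state_label(h) for h in self.hidden_states],
            obs_labels=[f"{p.ttt}-{p.ctrl}-{'yes' if p.comp else 'no'}" for p in PERF_STATES],
        )
        tab.validate()
        return tab

    @staticmethod
    def state_label(h: HiddenState) -> str:
        n = "/".join(h.ranges.labels())
        return f"fat={'yes' if h.fatigued else 'no'};n={n};lr={LEARNRATES[h.learnrate]}"

    # -- structural counts ---------------------------------------------------

    @staticmethod
    def count_full_states(relaxed: bool = True) -> int:
        return sum(1 for _ in enumerate_full_states(relaxed=relaxed))

    @staticmethod
    def stretch_image() -> set[int]:
        """All stretch values attainable over actions x admissible profiles."""
        return {
            stretch_of(a, prof)
            for a in ACTIONS[:-1]
            for prof in admissible_profiles()
        }
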