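"""Synthetic-patient generator and closed-loop session runner.

Patients are simulated from the same parametric family as the planning
model but with independently settable pace parameters, which supports both
consistency checks (model-matched patients) and robustness probing.  An
*episode* runs the policy/filter loop until the controller issues stop (or a
trial cap is hit); between episodes fatigue resets while the patient's
ranges — and the filtered belief over them — carry over.

A scripted-observation mode replays a fixed performance sequence
regardless of the chosen actions, mirroring manual-entry walk-throughs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import belief as bf
from .model import (
    ACTIONS,
    PERF_STATES,
    Action,
    DynamicsSpec,
    HiddenState,
    PerformanceState,
    RangeProfile,
    RehabModel,
    RewardSpec,
    stretch_of,
)
from .belief import BeliefState
from .solver import Policy, best_action, perseus_solve, sample_beliefs

__all__ = [
    "PatientProfile",
    "PatientState",
    "TrialRecord",
    "EpisodeLog",
    "SessionLog",
    "step",
    "run_episode",
    "run_session",
    "example1_script",
    "example2_script",
    "sweep_stop_cost",
    "sweep_fatigue_shift",
]


@dataclass(frozen=True)
class PatientProfile:
    """Ground-truth synthetic patient: starting ranges, trait, dynamics."""

    ranges: RangeProfile
    learnrate: int = 1  # 0 = lo, 1 = med, 2 = hi
    dynamics: DynamicsSpec | None = None  # defaults to the model's own

    def __post_init__(self) -> None:
        prof = (
            self.ranges
            if isinstance(self.ranges, RangeProfile)
            else RangeProfile(*self.ranges)
        )
        object.__setattr__(self, "ranges", prof)
        if not prof.admissible:
            raise ValueError(f"inadmissible patient ranges {prof}")
        if self.learnrate not in (0, 1, 2):
            raise ValueError("learnrate must be 0, 1 or 2")


@dataclass
class PatientState:
    """Mutable simulated patient condition during a session."""

    fatigued: bool
    ranges: RangeProfile
    learnrate: int

    def hidden(self) -> HiddenState:
        return HiddenState(self.fatigued, self.ranges, self.learnrate)


@dataclass(frozen=True)
class TrialRecord:
    episode: int
    trial: int
    action: Action
    stretch: int
    perf: PerformanceState
    p_fatigue: float  # filtered fatigue belief after the update
    reward: float
    true_fatigued: bool
    true_ranges: RangeProfile


@dataclass
class EpisodeLog:
    episode: int
    trials: list[TrialRecord] = field(default_factory=list)
    stopped: bool = False

    @property
    def run_length(self) -> int:
        return len(self.trials)


@dataclass
class SessionLog:
    episodes: list[EpisodeLog] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ep in self.episodes:
            for t in ep.trials:
                rows.append(
                    {
                        "episode": ep.episode,
                        "trial": t.trial,
                        "action_d": t.action.a_d,
                        "action_r": t.action.a_r,
                        "stretch": t.stretch,
                        "ttt": t.perf.ttt,
                        "ctrl": t.perf.ctrl,
                        "comp": "yes" if t.perf.comp else "no",
                        "P_fatigue": t.p_fatigue,
                        "reward": t.reward,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "episode",
                "trial",
                "action_d",
                "action_r",
                "stretch",
                "ttt",
                "ctrl",
                "comp",
                "P_fatigue",
                "reward",
            ],
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# One stochastic patient step
# ---------------------------------------------------------------------------


def step(
    model: RehabModel,
    state: PatientState,
    action: Action,
    rng: np.random.Generator,
    dynamics: DynamicsSpec | None = None,
) -> tuple[PatientState, PerformanceState]:
    """Sample the patient's next condition and observed performance.

    Performance is drawn from the pace composition at the trial's stretch,
    the fatigue hazard fires independently, and range growth is conditioned
    on the trial's success; all with ``dynamics`` (the patient's own pace
    parameters) falling back to the model's.
    """
    if action.is_stop:
        raise ValueError("step is undefined for the stop action")
    dyn_model = (
        model
        if dynamics is None
        else RehabModel(dynamics=dynamics, reward_spec=model.reward_spec)
    )
    hidden = state.hidden()
    p_perf = dyn_model.transition_performance(hidden, action)
    perf = PERF_STATES[int(rng.choice(len(PERF_STATES), p=p_perf))]
    s = stretch_of(action, state.ranges)
    p_fat = dyn_model.transition_fatigue(hidden, action, s)
    fat_next = bool(rng.random() < p_fat)
    ranges_dist = dyn_model.transition_ranges(hidden, action, perf)
    profs = list(ranges_dist)
    probs = np.array([ranges_dist[p] for p in profs])
    ranges_next = profs[int(rng.choice(len(profs), p=probs))]
    return PatientState(fat_next, ranges_next, state.learnrate), perf


# ---------------------------------------------------------------------------
# Closed-loop episodes and sessions
# ---------------------------------------------------------------------------


def example1_script(n_good: int = 6) -> Callable[[int, Action], PerformanceState]:
    """Worked-example narrative 1: an able patient who starts compensating.

    The patient reaches every commanded target in normal time with maximum
    control; after ``n_good`` clean trials every further trial shows a
    compensatory movement.  The controller is expected to stop after the
    compensation repeats.  This is a synthetic stand-in encoding only the
    narrative pattern; the original trial-by-trial sequence is unpublished.
    """
    good = PerformanceState("norm", "max", False)
    comp = PerformanceState("norm", "max", True)

    def script(trial: int, action: Action) -> PerformanceState:
        return good if trial < n_good else comp

    return script


def example2_script() -> Callable[[int, Action], PerformanceState]:
    """Worked-example narrative 2: a weak patient who cannot reach d3.

    The patient performs cleanly at d1/d2 but fails every d3 attempt at
    zero resistance — first with minimum control and no compensation, then
    (from the third failure) with a compensatory movement.  The controller
    is expected to stop once the failed reach is paired with compensation.
    This is a synthetic stand-in encoding only the narrative pattern; the
    original trial-by-trial sequence is unpublished.
    """
    good = PerformanceState("norm", "max", False)
    fail_min = PerformanceState("none", "min", False)
    fail_comp = PerformanceState("none", "min", True)
    n_fail = 0

    def script(trial: int, action: Action) -> PerformanceState:
        nonlocal n_fail
        if action.a_d == 3:
            n_fail += 1
            return fail_min if n_fail <= 2 else fail_comp
        return good

    return script


def run_episode(
    policy: Policy,
    model: RehabModel,
    patient: PatientState,
    b: BeliefState,
    max_trials: int = 50,
    rng: np.random.Generator | None = None,
    scripted: Sequence[PerformanceState]
    | Callable[[int, Action], PerformanceState | None]
    | None = None,
    patient_dynamics: DynamicsSpec | None = None,
    episode_index: int = 0,
) -> tuple[EpisodeLog, PatientState, BeliefState]:
    """Run best_action -> observe -> filter until stop or the trial cap.

    With ``scripted`` observations the patient's performance is replayed
    (manual-entry mode) instead of being sampled: either a fixed sequence,
    or a callable ``(trial, action) -> PerformanceState | None`` for
    narratives that react to the commanded target (None ends the episode).
    The hidden patient state does not evolve in scripted mode.  Returns the
    episode log plus the patient state and belief at the episode boundary
    (after rest: fatigue reset, ranges carried over).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    log = EpisodeLog(episode=episode_index)
    for trial in range(max_trials):
        action = best_action(policy, b)
        if action.is_stop:
            log.stopped = True
            break
        if scripted is not None:
            if callable(scripted):
                perf = scripted(trial, action)
            else:
                perf = scripted[trial] if trial < len(scripted) else None
            if perf is None:
                break
            nxt = patient  # scripted mode does not evolve the patient
        else:
            nxt, perf = step(model, patient, action, rng, patient_dynamics)
        reward = model.reward(patient.hidden(), action, perf)
        s = stretch_of(action, patient.ranges)
        b = bf.update(b, action, perf)
        log.trials.append(
            TrialRecord(
                episode=episode_index,
                trial=trial,
                action=action,
                stretch=s,
                perf=perf,
                p_fatigue=bf.marginal(b, "fatigue")["yes"],
                reward=reward,
                true_fatigued=patient.fatigued,
                true_ranges=patient.ranges,
            )
        )
        patient = nxt
    # episode boundary: rest — fatigue recovers, ranges carry over
    patient = PatientState(False, patient.ranges, patient.learnrate)
    b = bf.rest(b)
    return log, patient, b


def run_session(
    policy: Policy,
    model: RehabModel,
    profile: PatientProfile,
    n_episodes: int,
    initial_belief: BeliefState,
    max_trials: int = 50,
    seed: int = 0,
) -> SessionLog:
    """Chain episodes with the reset/carry-over boundary semantics."""
    rng = np.random.default_rng(seed)
    patient = PatientState(False, profile.ranges, profile.learnrate)
    b = initial_belief
    session = SessionLog()
    for ep in range(n_episodes):
        log, patient, b = run_episode(
            policy,
            model,
            patient,
            b,
            max_trials=max_trials,
            rng=rng,
            patient_dynamics=profile.dynamics,
            episode_index=ep,
        )
        session.episodes.append(log)
    return session


# ---------------------------------------------------------------------------
# Sweep experiments
# ---------------------------------------------------------------------------


def _mean_run_length(
    model: RehabModel,
    policy: Policy,
    n_reps: int,
    seed: int,
    max_trials: int,
    profile_concentration: float,
) -> float:
    """Mean first-episode run length over randomly drawn patients."""
    rng = np.random.default_rng(seed)
    profiles = list(bf.admissible_profiles())
    lengths = []
    for _ in range(n_reps):
        prof = profiles[int(rng.integers(len(profiles)))]
        lr = int(rng.integers(3))
        patient = PatientState(False, prof, lr)
        b0 = bf.initial_belief(
            model, prof, profile_concentration=profile_concentration
        )
        ep_rng = np.random.default_rng(rng.integers(2**31 - 1))
        log, _, _ = run_episode(
            policy, model, patient, b0, max_trials=max_trials, rng=ep_rng
        )
        lengths.append(log.run_length)
    return float(np.mean(lengths))


def _solve_for(
    model: RehabModel,
    seed: int,
    belief_points: int,
    max_alphas: int,
    iterations: int,
) -> Policy:
    beliefs = sample_beliefs(model, belief_points, seed=seed)
    return perseus_solve(
        model, beliefs, max_alphas=max_alphas, iterations=iterations, seed=seed
    )


def sweep_stop_cost(
    costs: Sequence[float],
    n_reps: int,
    seed: int,
    dynamics: DynamicsSpec | None = None,
    reward_spec: RewardSpec | None = None,
    belief_points: int = 500,
    max_alphas: int = 60,
    iterations: int = 60,
    max_trials: int = 50,
    profile_concentration: float = 0.85,
) -> pd.DataFrame:
    """Mean episode run length as the stop-action cost varies.

    A policy is re-solved for every cost; a dearer stop makes the
    controller tolerate higher fatigue beliefs, lengthening episodes.
    """
    base = reward_spec if reward_spec is not None else RewardSpec()
    rows = []
    for cost in costs:
        if cost < 0:
            raise ValueError("stop cost must be >= 0")
        spec = RewardSpec(
            r_goal=base.r_goal,
            r_stretch=base.r_stretch,
            r_perform=base.r_perform,
            c_stop=float(cost),
            gamma=base.gamma,
        )
        model = RehabModel(dynamics=dynamics, reward_spec=spec)
        policy = _solve_for(model, seed, belief_points, max_alphas, iterations)
        mean_len = _mean_run_length(
            model, policy, n_reps, seed + 1, max_trials, profile_concentration
        )
        rows.append({"stop_cost": float(cost), "mean_run_length": mean_len})
    return pd.DataFrame(rows)


def sweep_fatigue_shift(
    shifts: Sequence[float],
    n_reps: int,
    seed: int,
    dynamics: DynamicsSpec | None = None,
    reward_spec: RewardSpec | None = None,
    belief_points: int = 500,
    max_alphas: int = 60,
    iterations: int = 60,
    max_trials: int = 50,
    profile_concentration: float = 0.85,
) -> pd.DataFrame:
    """Mean episode run length as the fatigue pace curve shifts right.

    A positive shift raises the stretch at which fatigue onset becomes
    likely — the patient is modelled (and simulated) as fatiguing less
    easily — which lengthens episodes.
    """
    from .model import default_dynamics

    base = dynamics if dynamics is not None else default_dynamics()
    rows = []
    for shift in shifts:
        paces = dict(base.paces)
        paces["fatigue"] = base.pace("fatigue").shifted(float(shift))
        dyn = DynamicsSpec(
            paces=paces, p_up=base.p_up, stretch_up_max=base.stretch_up_max
        )
        model = RehabModel(dynamics=dyn, reward_spec=reward_spec)
        policy = _solve_for(model, seed, belief_points, max_alphas, iterations)
        mean_len = _mean_run_length(
            model, policy, n_reps, seed + 1, max_trials, profile_concentration
        )
        rows.append({"fatigue_shift": float(shift), "mean_run_length": mean_len})
    return pd.DataFrame(rows)
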