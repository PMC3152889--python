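"""Continuous-resistance controller with Beta-mixture success models.

Extends the discrete three-level resistance to a continuum u in [0, u_max].
The probability of completing an exercise at resistance u is modelled by two
monotone non-increasing success curves — one for a fatigued patient, one for
a non-fatigued patient — mixed by the current belief that the patient is
fatigued.  The next resistance is the largest grid value at which the
mixture is at least 0.5; after each observed outcome both curves and the
fatigue belief are updated by (tempered) Bayes' rule.

Each curve is a latent-threshold model: the patient has an unknown failure
threshold, a fraction x of u_max distributed a priori as Beta(a, b); a trial
at resistance u succeeds with probability sigmoid((x * u_max - u) / tau).
The success curve is the posterior-predictive success probability, which is
Beta-shaped, smooth, and non-increasing in u.  Outcome evidence multiplies
the threshold posterior by the (responsibility- and pseudo-count-weighted)
likelihood, so successes push the curves up and failures pull them down.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SuccessCurve",
    "SuccessModel",
    "ContinuousOutcome",
    "mixture_success_prob",
    "select_resistance",
    "update_on_outcome",
    "run_adaptive_session",
    "default_success_model",
]


@dataclass(frozen=True)
class SuccessCurve:
    """Posterior over the failure-threshold fraction plus the outcome link.

    ``grid`` holds threshold fractions x in [0, 1]; ``weights`` the posterior
    probability of each; ``tau`` the resistance scale of the success link.
    """

    u_max: float
    grid: np.ndarray
    weights: np.ndarray
    tau: float = 0.4

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if g.shape != w.shape or g.ndim != 1:
            raise ValueError("grid and weights must be matching 1-d arrays")
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive mass")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "weights", w / w.sum())

    @classmethod
    def from_beta(
        cls,
        a: float,
        b: float,
        u_max: float = 20.0,
        tau: float = 0.4,
        n_grid: int = 201,
    ) -> "SuccessCurve":
        """Discretised Beta(a, b) prior over the threshold fraction."""
        if a <= 0 or b <= 0:
            raise ValueError("Beta shape parameters must be positive")
        x = np.linspace(0.0, 1.0, n_grid)
        edges = np.concatenate([[0.0], (x[1:] + x[:-1]) / 2.0, [1.0]])
        w = np.diff(stats.beta.cdf(edges, a, b))
        return cls(u_max=u_max, grid=x, weights=w, tau=tau)

    @classmethod
    def point_mass(
        cls, threshold_u: float, u_max: float = 20.0, tau: float = 0.4
    ) -> "SuccessCurve":
        """Degenerate curve with a known threshold (useful for tests)."""
        return cls(
            u_max=u_max,
            grid=np.array([threshold_u / u_max]),
            weights=np.array([1.0]),
            tau=tau,
        )

    def success_likelihood(self, u: float) -> np.ndarray:
        """P(success at u | threshold fraction x) on the grid."""
        z = (self.grid * self.u_max - u) / self.tau
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def __call__(self, u: float) -> float:
        """Posterior-predictive success probability at resistance u."""
        return float(self.weights @ self.success_likelihood(u))

    def tempered(self, u: float, success: bool, exponent: float) -> "SuccessCurve":
        """Posterior after one outcome, likelihood tempered by ``exponent``."""
        if exponent == 0.0:
            return self
        lik = self.success_likelihood(u)
        if not success:
            lik = 1.0 - lik
        w = self.weights * np.power(np.maximum(lik, 1e-300), exponent)
        total = w.sum()
        if total <= 0:
            return self  # outcome carries no usable evidence; keep the prior
        return replace(self, weights=w / total)


@dataclass(frozen=True)
class SuccessModel:
    """Fatigue-conditional success curves plus the fatigue belief.

    ``kappa`` is the pseudo-count weight of one outcome: 1 is a full Bayes
    update, 0 freezes the model.
    """

    curve_notfat: SuccessCurve
    curve_fat: SuccessCurve
    fatigue_belief: float = 0.1
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fatigue_belief <= 1.0):
            raise ValueError("fatigue_belief must lie in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.curve_notfat.u_max != self.curve_fat.u_max:
            raise ValueError("both curves must share u_max")

    @property
    def u_max(self) -> float:
        return self.curve_notfat.u_max


@dataclass(frozen=True)
class ContinuousOutcome:
    """One continuous-resistance trial: resistance and success flag."""

    u: float
    success: bool


def default_success_model(
    u_max: float = 20.0,
    tau: float = 0.4,
    fatigue_belief: float = 0.1,
    kappa: float = 1.0,
) -> SuccessModel:
    """Default priors: non-fatigued threshold centred mid-range, fatigued
    threshold shifted toward low resistance (first-order stochastically
    dominated, so the fatigued curve starts below the non-fatigued one).
    """
    return SuccessModel(
        curve_notfat=SuccessCurve.from_beta(6.0, 6.0, u_max=u_max, tau=tau),
        curve_fat=SuccessCurve.from_beta(3.5, 8.0, u_max=u_max, tau=tau),
        fatigue_belief=fatigue_belief,
        kappa=kappa,
    )


def mixture_success_prob(model: SuccessModel, u: float) -> float:
    """Belief-weighted mixture success probability at resistance u."""
    if not (0.0 <= u <= model.u_max):
        raise ValueError(f"resistance {u} outside [0, {model.u_max}]")
    fb = model.fatigue_belief
    return (1.0 - fb) * model.curve_notfat(u) + fb * model.curve_fat(u)


def select_resistance(model: SuccessModel, grid_step: float = 0.1) -> float:
    """Largest grid resistance whose mixture success probability is >= 0.5.

    Falls back to the grid minimum (0) when the mixture is below 0.5
    everywhere.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    n = int(round(model.u_max / grid_step))
    grid = np.round(np.arange(n + 1) * grid_step, 10)
    probs = np.array([mixture_success_prob(model, u) for u in grid])
    ok = np.flatnonzero(probs >= 0.5)
    if ok.size == 0:
        return float(grid[0])
    return float(grid[ok[-1]])


def update_on_outcome(model: SuccessModel, outcome: ContinuousOutcome) -> SuccessModel:
    """Tempered Bayes update of the fatigue belief and both curves.

    The fatigue belief moves by the (kappa-tempered) likelihood ratio of the
    outcome under the two curves; each curve is then updated with exponent
    kappa times its fatigue responsibility, so evidence is shared in
    proportion to how likely the patient was in each condition.
    """
    if not (0.0 <= outcome.u <= model.u_max):
        raise ValueError(f"resistance {outcome.u} outside [0, {model.u_max}]")
    if model.kappa == 0.0:
        return model
    p_n = model.curve_notfat(outcome.u)
    p_y = model.curve_fat(outcome.u)
    l_n = p_n if outcome.success else 1.0 - p_n
    l_y = p_y if outcome.success else 1.0 - p_y
    fb = model.fatigue_belief
    k = model.kappa
    wy = fb * max(l_y, 1e-300) ** k
    wn = (1.0 - fb) * max(l_n, 1e-300) ** k
    post_fat = wy / (wy + wn) if (wy + wn) > 0 else fb
    new_nf = model.curve_notfat.tempered(
        outcome.u, outcome.success, k * (1.0 - post_fat)
    )
    new_f = model.curve_fat.tempered(outcome.u, outcome.success, k * post_fat)
    return SuccessModel(
        curve_notfat=new_nf,
        curve_fat=new_f,
        fatigue_belief=post_fat,
        kappa=model.kappa,
    )


def run_adaptive_session(
    model: SuccessModel,
    patient_success_curve: Callable[[float], float],
    fatigue_threshold: float = 0.6,
    max_trials: int = 50,
    seed: int = 0,
    grid_step: float = 0.1,
    scripted_outcomes: list[bool] | None = None,
) -> pd.DataFrame:
    """Select -> observe -> update loop until the fatigue threshold trips.

    Outcomes are Bernoulli draws from ``patient_success_curve`` at the
    selected resistance (or replayed from ``scripted_outcomes``).  Returns a
    table with one row per trial: u, outcome, fatigue_belief, next_u.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for trial in range(max_trials):
        if model.fatigue_belief >= fatigue_threshold:
            break
        u = select_resistance(model, grid_step)
        if scripted_outcomes is not None:
            if trial >= len(scripted_outcomes):
                break
            success = bool(scripted_outcomes[trial])
        else:
            success = bool(rng.random() < patient_success_curve(u))
        model = update_on_outcome(model, ContinuousOutcome(u, success))
        rows.append(
            {
                "trial": trial,
                "u": u,
                "success": success,
                "fatigue_belief": model.fatigue_belief,
                "next_u": select_resistance(model, grid_step),
            }
        )
    return pd.DataFrame(
        rows, columns=["trial", "u", "success", "fatigue_belief", "next_u"]
    )
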