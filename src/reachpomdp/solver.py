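"""Randomized point-based value iteration with a bounded alpha-vector set.

The solver follows the Perseus scheme: sample a set of reachable beliefs by
random simulation, then at each stage improve the value at randomly chosen
belief points via point-based Bellman backups against the previous stage's
value function until every sampled belief has improved.  The alpha-vector
set is capped; when the cap is exceeded the vector that is maximal at the
fewest sampled beliefs is dropped (ties broken by age).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .model import ACTIONS, Action, RehabModel, TabularPOMDP
from .belief import BeliefState, all_initial_beliefs

logger = logging.getLogger(__name__)

__all__ = [
    "AlphaVector",
    "Policy",
    "sample_beliefs",
    "perseus_solve",
    "best_action",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class AlphaVector:
    """A linear value function over hidden states with its greedy action."""

    values: np.ndarray
    action: int  # action index

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError("alpha vector contains non-finite values")
        object.__setattr__(self, "values", v)


@dataclass
class Policy:
    """Bounded set of alpha vectors; value(b) = max_i dot(b, alpha_i).

    ``stage_min_values`` records, per Perseus stage, the minimum value over
    the sampled beliefs at the *start* of the stage (solver diagnostic).
    """

    alphas: list[AlphaVector]
    action_labels: list[str] = field(default_factory=list)
    stage_min_values: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.alphas:
            raise ValueError("policy needs at least one alpha vector")

    def _matrix(self) -> np.ndarray:
        return np.stack([a.values for a in self.alphas])

    def value_at(self, b: BeliefState | np.ndarray) -> float:
        probs = b.probs if isinstance(b, BeliefState) else np.asarray(b)
        return float((self._matrix() @ probs).max())

    def best_alpha(self, b: BeliefState | np.ndarray) -> AlphaVector:
        probs = b.probs if isinstance(b, BeliefState) else np.asarray(b)
        dots = self._matrix() @ probs
        top = dots.max()
        # deterministic tie-break: among maximizing vectors, lowest action index
        candidates = [
            self.alphas[i] for i in np.flatnonzero(dots >= top - _TIE_TOL)
        ]
        return min(candidates, key=lambda a: a.action)

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "action_labels": list(self.action_labels),
            "alphas": [
                {"action": a.action, "values": a.values.tolist()}
                for a in self.alphas
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "Policy":
        if text_or_path.lstrip().startswith("{"):
            payload = json.loads(text_or_path)
        else:
            with open(text_or_path) as fh:
                payload = json.load(fh)
        alphas = [
            AlphaVector(np.asarray(a["values"], dtype=float), int(a["action"]))
            for a in payload["alphas"]
        ]
        return cls(alphas=alphas, action_labels=list(payload.get("action_labels", [])))


def best_action(policy: Policy, b: BeliefState) -> Action:
    """Greedy action of the maximizing alpha vector at b."""
    return ACTIONS[policy.best_alpha(b).action]


# ---------------------------------------------------------------------------
# Belief sampling
# ---------------------------------------------------------------------------


def sample_beliefs(
    model: RehabModel,
    n_points: int,
    seed: int,
    steps_per_episode: int = 12,
    fatigue_no_prob: float = 0.95,
    profile_concentration: float = 0.85,
) -> list[BeliefState]:
    """Beliefs reachable by random simulation from the 20 initial beliefs.

    Episodes round-robin over the initial range possibilities; within an
    episode a random set-target action is taken, the hidden state is sampled
    forward, and the filtered belief after each (action, observation) pair is
    collected.  Reproducible for a given seed.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    inits = all_initial_beliefs(model, fatigue_no_prob, profile_concentration)
    tab = model.tabular
    H = tab.n_states
    out: list[BeliefState] = []
    episode = 0
    while len(out) < n_points:
        b = inits[episode % len(inits)]
        episode += 1
        out.append(b)
        # sample a concrete hidden state to drive the observations
        h_idx = rng.choice(H, p=b.probs)
        for _ in range(steps_per_episode):
            if len(out) >= n_points:
                break
            ai = int(rng.integers(0, len(ACTIONS) - 1))  # set-target only
            flat = tab.joint[ai, h_idx].ravel()
            draw = rng.choice(flat.size, p=flat)
            o_idx, h_next = divmod(draw, H)
            post = b.probs @ tab.joint[ai, :, o_idx, :]
            total = post.sum()
            if total <= 0.0:
                break
            b = BeliefState(model, post / total)
            out.append(b)
            h_idx = int(h_next)
    return out[:n_points]


# ---------------------------------------------------------------------------
# Perseus
# ---------------------------------------------------------------------------


def _backup(
    tab: TabularPOMDP,
    b: np.ndarray,
    G: np.ndarray,
) -> tuple[np.ndarray, int, float]:
    """Point-based Bellman backup at belief b against the stage value set.

    G[a] has shape (O, H, I): G[a][o, h, i] = sum_h' P(o, h' | h, a) alpha_i(h').
    Returns the backed-up vector, its action, and its value at b.
    """
    A, H = tab.rho.shape
    best_val = -np.inf
    best_vec: np.ndarray | None = None
    best_act = 0
    for a in range(A):
        scores = np.einsum("h,ohi->oi", b, G[a])  # (O, I)
        picks = scores.argmax(axis=1)
        vec = tab.rho[a] + tab.gamma * G[a][np.arange(G[a].shape[0]), :, picks].sum(
            axis=0
        )
        val = float(vec @ b)
        if val > best_val + _TIE_TOL:
            best_val, best_vec, best_act = val, vec, a
    assert best_vec is not None
    return best_vec, best_act, best_val


def perseus_solve(
    model: RehabModel | TabularPOMDP,
    beliefs: list[BeliefState] | np.ndarray,
    max_alphas: int = 60,
    iterations: int = 60,
    seed: int = 0,
    tol: float = 1e-9,
) -> Policy:
    """Perseus sweep with a hard cap on the alpha-vector set size.

    The value at every sampled belief is non-decreasing across stages as
    long as the cap does not force pruning of a still-needed vector; pruning
    stalls are logged and not fatal.
    """
    if max_alphas < 1 or iterations < 1:
        raise ValueError("max_alphas and iterations must be >= 1")
    tab = model.tabular if isinstance(model, RehabModel) else model
    rng = np.random.default_rng(seed)
    if isinstance(beliefs, np.ndarray):
        B = np.asarray(beliefs, dtype=float)
    else:
        B = np.stack([b.probs for b in beliefs])
    N, H = B.shape
    A = tab.n_actions

    # pessimistic initial value: collect-the-worst-reward-forever
    r_min = float(tab.rho.min())
    alpha_mat = np.full((1, H), r_min / (1.0 - tab.gamma))
    alpha_act = np.zeros(1, dtype=int)
    birth = np.zeros(1, dtype=int)  # age for pruning tie-breaks

    M = tab.joint  # (A, H, O, H)
    stage_min: list[float] = []
    for stage in range(iterations):
        # G[a][o, h, i] = sum_h' P(o, h' | h, a) alpha_i(h'), fixed per stage
        G = np.stack([np.einsum("hoj,ij->ohi", M[a], alpha_mat) for a in range(A)])
        V_prev = (B @ alpha_mat.T).max(axis=1)  # (N,)
        stage_min.append(float(V_prev.min()))
        improved = np.zeros(N, dtype=bool)
        new_vecs: list[np.ndarray] = []
        new_acts: list[int] = []
        order = rng.permutation(N)
        for idx in order:
            if improved[idx]:
                continue
            vec, act, val = _backup(tab, B[idx], G)
            if val < V_prev[idx] - tol:
                # keep the previous maximizing vector for this belief
                keep = int((alpha_mat @ B[idx]).argmax())
                vec, act = alpha_mat[keep].copy(), int(alpha_act[keep])
            new_vecs.append(vec)
            new_acts.append(act)
            improved |= B @ vec >= V_prev - tol
        alpha_mat = np.stack(new_vecs)
        alpha_act = np.asarray(new_acts, dtype=int)
        birth = np.full(len(new_vecs), stage, dtype=int)
        if alpha_mat.shape[0] > max_alphas:
            alpha_mat, alpha_act, birth = _prune(
                alpha_mat, alpha_act, birth, B, max_alphas
            )
            V_now = (B @ alpha_mat.T).max(axis=1)
            if (V_now < V_prev - 1e-6).any():
                logger.info(
                    "perseus stage %d: cap pruning reduced value at %d beliefs",
                    stage,
                    int((V_now < V_prev - 1e-6).sum()),
                )
    stage_min.append(float((B @ alpha_mat.T).max(axis=1).min()))
    labels = list(tab.action_labels)
    return Policy(
        alphas=[AlphaVector(v, int(a)) for v, a in zip(alpha_mat, alpha_act)],
        action_labels=labels,
        stage_min_values=stage_min,
    )


def _prune(
    alpha_mat: np.ndarray,
    alpha_act: np.ndarray,
    birth: np.ndarray,
    B: np.ndarray,
    max_alphas: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Keep the vectors that win at the most sampled beliefs.

    Vectors are ranked by the number of beliefs at which they are maximal
    (ties by age: older vectors are dropped first); the cap is enforced by
    dropping from the bottom of that ranking.
    """
    scores = B @ alpha_mat.T  # (N, I)
    winners = scores.argmax(axis=1)
    counts = np.bincount(winners, minlength=alpha_mat.shape[0])
    # sort: most wins first; among equals, younger (larger birth) first
    order = sorted(
        range(alpha_mat.shape[0]),
        key=lambda i: (-counts[i], -birth[i], i),
    )
    keep = sorted(order[:max_alphas])
    return alpha_mat[keep], alpha_act[keep], birth[keep]
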