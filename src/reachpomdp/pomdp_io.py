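"""Cassandra ``.pomdp`` text export/import for cross-checking.

The exporter writes any :class:`TabularPOMDP` whose joint kernel factorises
as T(s'|s,a) * O(o|a,s') — which holds for toys constructed that way and is
verified numerically before writing.  The flat 82,944-state rehabilitation
view is far too large for explicit tables (and its observation model only
factorises over *full* states), so it is exported header-only: the
preamble carries the exact state/action/observation counts for structural
cross-checks and the tables are omitted with an explanatory comment.
"""

from __future__ import annotations

import numpy as np

from .model import (
    ACTIONS,
    PERF_STATES,
    RehabModel,
    TabularPOMDP,
)

__all__ = ["export_pomdp", "write_pomdp", "parse_pomdp", "export_full_model_header"]

_FACTOR_TOL = 1e-9


def _factorise(tab: TabularPOMDP) -> tuple[np.ndarray, np.ndarray]:
    """Split joint P(o,s'|s,a) into T(s'|s,a) and O(o|a,s'); verify exact."""
    T = tab.joint.sum(axis=2)  # (A, S, S')
    A, S, O, _ = tab.joint.shape
    Omat = np.zeros((A, S, O))  # O(o | a, s')
    for a in range(A):
        for s2 in range(S):
            mass = tab.joint[a, :, :, s2]  # (S, O)
            col = mass.sum(axis=0)
            total = col.sum()
            if total > 0:
                Omat[a, s2] = col / total
            else:
                Omat[a, s2, 0] = 1.0  # unreachable state: arbitrary valid row
    recon = np.einsum("asj,ajo->asoj", T, Omat)
    if not np.allclose(recon, tab.joint, atol=_FACTOR_TOL):
        raise ValueError(
            "joint kernel does not factorise as T(s'|s,a) * O(o|a,s'); "
            "Cassandra export would misrepresent the model"
        )
    return T, Omat


def write_pomdp(tab: TabularPOMDP, path: str, header_only: bool = False) -> None:
    """Write a TabularPOMDP in Cassandra format.

    Rewards are written as R: <a> : <s> : * : * <val> (expected immediate
    reward, which is what the container stores).
    """
    A, S, O, _ = tab.joint.shape
    lines = [
        f"discount: {tab.gamma}",
        "values: reward",
        f"states: {S}",
        f"actions: {A}",
        f"observations: {O}",
        "",
    ]
    if header_only:
        lines.append("# tables omitted: model too large for explicit enumeration")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        return
    T, Omat = _factorise(tab)
    for a in range(A):
        for s in range(S):
            for s2 in np.flatnonzero(T[a, s] > 0):
                lines.append(f"T: {a} : {s} : {s2} {T[a, s, s2]:.12g}")
    for a in range(A):
        for s2 in range(S):
            for o in np.flatnonzero(Omat[a, s2] > 0):
                lines.append(f"O: {a} : {s2} : {o} {Omat[a, s2, o]:.12g}")
    for a in range(A):
        for s in np.flatnonzero(np.abs(tab.rho[a]) > 0):
            lines.append(f"R: {a} : {s} : * : * {tab.rho[a, s]:.12g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def parse_pomdp(path: str) -> TabularPOMDP:
    """Parse a file written by :func:`write_pomdp` (numeric identifiers)."""
    gamma = 0.95
    S = A = O = 0
    T = Omat = R = None
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("discount:"):
                gamma = float(line.split(":", 1)[1])
            elif line.startswith("states:"):
                S = int(line.split(":", 1)[1])
            elif line.startswith("actions:"):
                A = int(line.split(":", 1)[1])
            elif line.startswith("observations:"):
                O = int(line.split(":", 1)[1])
            elif line.startswith("T:"):
                if T is None:
                    T = np.zeros((A, S, S))
                head, prob = line.rsplit(" ", 1)
                _, a, s, s2 = [p.strip() for p in head.split(":")]
                T[int(a), int(s), int(s2)] = float(prob)
            elif line.startswith("O:"):
                if Omat is None:
                    Omat = np.zeros((A, S, O))
                head, prob = line.rsplit(" ", 1)
                _, a, s2, o = [p.strip() for p in head.split(":")]
                Omat[int(a), int(s2), int(o)] = float(prob)
            elif line.startswith("R:"):
                if R is None:
                    R = np.zeros((A, S))
                head, val = line.rsplit(" ", 1)
                parts = [p.strip() for p in head.split(":")]
                R[int(parts[1]), int(parts[2])] = float(val)
    if T is None:
        T = np.zeros((A, S, S))
    if Omat is None:
        Omat = np.zeros((A, S, O))
        Omat[:, :, 0] = 1.0
    if R is None:
        R = np.zeros((A, S))
    joint = np.einsum("asj,ajo->asoj", T, Omat)
    return TabularPOMDP(joint=joint, rho=R, gamma=gamma)


def export_full_model_header(model: RehabModel, path: str) -> None:
    """Header-only export of the flat (relaxed) joint-state view."""
    n_full = model.count_full_states(relaxed=True)
    lines = [
        f"discount: {model.reward_spec.gamma}",
        "values: reward",
        f"states: {n_full}",
        f"actions: {len(ACTIONS)}",
        f"observations: {len(PERF_STATES)}",
        "",
        "# tables omitted: flat joint-state view kept for enumeration checks only",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def export_pomdp(
    model: RehabModel | TabularPOMDP,
    path: str,
    flat: bool = False,
    max_table_states: int = 2000,
) -> None:
    """Export a model for third-party solvers.

    ``flat=True`` writes the header of the 82,944-state joint view.
    Otherwise a TabularPOMDP (or the model's hidden-state tabular form) is
    written with full tables when small enough, header-only above
    ``max_table_states``.
    """
    if isinstance(model, RehabModel):
        if flat:
            export_full_model_header(model, path)
            return
        tab = model.tabular
    else:
        tab = model
    if tab.n_states > max_table_states:
        write_pomdp(tab, path, header_only=True)
        return
    try:
        write_pomdp(tab, path)
    except ValueError:
        # mixed-observability kernels condition o on the *previous* hidden
        # state, which Cassandra's O(o|a,s') cannot express; keep the header
        write_pomdp(tab, path, header_only=True)
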