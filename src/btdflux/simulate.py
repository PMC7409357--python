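"""Steady-state flux simulation: FBA, pFBA, LMOMA and MiMBL.

All four methods are explicit linear programs over the stoichiometric
matrix S, solved with HiGHS (dual simplex by default):

* **FBA** maximises the objective flux (biomass) subject to S·v = 0 and
  the flux bounds.
* **pFBA** is the two-stage parsimonious variant: fix the optimal growth
  z* from FBA, then minimise total absolute flux Σ|v_j| over the optimal
  face.  The wildtype flux distributions reported by this package are pFBA
  solutions.
* **LMOMA** predicts the flux state of a perturbed (mutant) network as the
  one minimising the Manhattan distance Σ|v_j − w_j| to a wildtype
  reference w.  Growth is an outcome, not a constraint.
* **MiMBL** minimises the distance between mutant and reference metabolite
  *turnovers* instead of fluxes: the turnover of metabolite i is
  t_i = ½ Σ_j |S_ij| (v_j⁺ + v_j⁻) over split fluxes, i.e. its total
  production rate.

A :class:`ReferenceState` bundles the wildtype pFBA flux vector w with the
turnovers τ computed from it; it is the baseline both for the distance
objectives and for strain-design modification factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import Condition, MetabolicModel, apply_condition, stoichiometric_matrix

__all__ = [
    "FluxSolution",
    "ReferenceState",
    "SolverError",
    "fba",
    "pfba",
    "reference_state",
    "lmoma",
    "mimbl",
    "turnovers",
    "feasibility_audit",
]

#: solver feasibility / optimality tolerance passed to HiGHS
SOLVER_TOL = 1e-9
#: default LP algorithm (HiGHS dual simplex)
SOLVER_METHOD = "highs-ds"


class SolverError(RuntimeError):
    """LP solver failed for a reason other than infeasibility/unboundedness."""


def _clamp_distance(value: float) -> float:
    """Distances below solver tolerance are numerically zero; report them so.

    Guarantees the identity property (unperturbed LMOMA/MiMBL distance is
    exactly 0) is not obscured by simplex round-off.
    """
    return 0.0 if abs(value) < 1e-9 else float(value)


@dataclass
class FluxSolution:
    """A flux vector with solver status and the LP objective value.

    ``objective_value`` is the value of the solved program's objective:
    growth for FBA/pFBA, the minimised distance for LMOMA/MiMBL.  For pFBA
    the minimised total absolute flux is reported in ``total_flux``.
    """

    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded
    method: str
    total_flux: Optional[float] = None
    growth: Optional[float] = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


@dataclass
class ReferenceState:
    """Wildtype flux vector w and metabolite turnovers τ under a condition."""

    fluxes: dict[str, float]
    turnovers: dict[str, float]
    condition_name: str = ""
    growth: float = 0.0

    def flux(self, reaction_id: str) -> float:
        return self.fluxes.get(reaction_id, 0.0)


def _status(res) -> str:
    if res.status == 0:
        return "optimal"
    if res.status == 2:
        return "infeasible"
    if res.status == 3:
        return "unbounded"
    raise SolverError(f"LP solver failure (status {res.status}): {res.message}")


def _bounds(model: MetabolicModel) -> tuple[np.ndarray, np.ndarray]:
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    return lb, ub


def _solve(c, A_ub, b_ub, A_eq, b_eq, bounds):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method=SOLVER_METHOD,
        options={
            "presolve": True,
            "primal_feasibility_tolerance": SOLVER_TOL,
            "dual_feasibility_tolerance": SOLVER_TOL,
        },
    )


def _empty(model: MetabolicModel, method: str, status: str) -> FluxSolution:
    return FluxSolution(
        fluxes={r.id: 0.0 for r in model.reactions},
        objective_value=float("nan"),
        status=status,
        method=method,
    )


def fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    condition: Optional[Condition] = None,
) -> FluxSolution:
    """Flux balance analysis: maximise the objective reaction's flux.

    Solves max c·v s.t. S·v = 0, lb ≤ v ≤ ub.  ``objective`` defaults to
    the model's biomass reaction; an optional ``condition`` is applied
    first.
    """
    if condition is not None:
        model = apply_condition(model, condition)
    if model.infeasible_marker:
        return _empty(model, "fba", "infeasible")
    obj = objective or model.objective_reaction
    rids = model.reaction_ids()
    if obj not in rids:
        raise KeyError(f"objective reaction {obj!r} not in model")
    S = stoichiometric_matrix(model)
    lb, ub = _bounds(model)
    c = np.zeros(len(rids))
    c[rids.index(obj)] = -1.0  # linprog minimises
    res = _solve(c, None, None, S, np.zeros(S.shape[0]), list(zip(lb, ub)))
    status = _status(res)
    if status != "optimal":
        return _empty(model, "fba", status)
    fluxes = dict(zip(rids, map(float, res.x)))
    g = fluxes[obj]
    return FluxSolution(fluxes=fluxes, objective_value=g, status="optimal", method="fba", growth=g)


def _split_bounds(lb: np.ndarray, ub: np.ndarray):
    """Bounds for a v = v⁺ − v⁻ split plus extra rows for one-signed bounds.

    v⁺ ∈ [0, max(ub,0)] and v⁻ ∈ [0, max(−lb,0)] already enforce
    lb ≤ v ≤ ub except when lb > 0 or ub < 0 (a forced flux); those cases
    get explicit inequality rows from the caller.
    """
    up = np.maximum(ub, 0.0)
    um = np.maximum(-lb, 0.0)
    return up, um


def _forced_rows(n: int, lb: np.ndarray, ub: np.ndarray, pos_block: int, neg_block: int, width: int):
    """Inequality rows enforcing v ≥ lb where lb>0 and v ≤ ub where ub<0."""
    rows = []
    rhs = []
    for j in range(n):
        if lb[j] > 0:
            row = np.zeros(width)
            row[pos_block + j] = -1.0
            row[neg_block + j] = 1.0
            rows.append(row)
            rhs.append(-lb[j])
        if ub[j] < 0:
            row = np.zeros(width)
            row[pos_block + j] = 1.0
            row[neg_block + j] = -1.0
            rows.append(row)
            rhs.append(ub[j])
    if not rows:
        return None, None
    return np.vstack(rows), np.array(rhs)


def pfba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    condition: Optional[Condition] = None,
    fraction_of_optimum: float = 1.0,
) -> FluxSolution:
    """Parsimonious FBA: minimal total flux at (a fraction of) optimal growth.

    Stage 1 solves FBA for the optimal growth z*; stage 2 minimises
    Σ_j (v_j⁺ + v_j⁻) subject to the steady state, the flux bounds and
    c·v ≥ fraction_of_optimum · z* (tolerance-guarded).  The returned
    ``objective_value`` is the achieved growth; the minimised total
    absolute flux is in ``total_flux``.
    """
    if condition is not None:
        model = apply_condition(model, condition)
        condition = None
    first = fba(model, objective=objective)
    if not first.optimal:
        return FluxSolution(first.fluxes, first.objective_value, first.status, "pfba")
    zstar = first.objective_value
    obj = objective or model.objective_reaction
    rids = model.reaction_ids()
    n = len(rids)
    S = stoichiometric_matrix(model)
    lb, ub = _bounds(model)
    up, um = _split_bounds(lb, ub)
    # variables: [v⁺ (n), v⁻ (n)]
    A_eq = sparse.hstack([S, -S]).tocsr()
    b_eq = np.zeros(S.shape[0])
    c = np.ones(2 * n)
    jobj = rids.index(obj)
    growth_row = np.zeros(2 * n)
    growth_row[jobj] = -1.0
    growth_row[n + jobj] = 1.0
    # no explicit relaxation: the solver's own feasibility tolerance (1e-9)
    # is the only slack on the growth pin, so pFBA growth == FBA growth
    b_growth = -(fraction_of_optimum * zstar)
    A_ub_rows = [growth_row]
    b_ub_vals = [b_growth]
    forced, frhs = _forced_rows(n, lb, ub, 0, n, 2 * n)
    if forced is not None:
        A_ub_rows.append(forced)
        b_ub_vals.append(frhs)
    A_ub = np.vstack([np.atleast_2d(r) for r in A_ub_rows])
    b_ub = np.concatenate([np.atleast_1d(v) for v in b_ub_vals])
    bounds = [(0.0, u) for u in up] + [(0.0, u) for u in um]
    res = _solve(c, A_ub, b_ub, A_eq, b_eq, bounds)
    status = _status(res)
    if status != "optimal":
        return _empty(model, "pfba", status)
    v = res.x[:n] - res.x[n:]
    fluxes = dict(zip(rids, map(float, v)))
    g = fluxes[obj]
    return FluxSolution(
        fluxes=fluxes,
        objective_value=g,
        status="optimal",
        method="pfba",
        total_flux=float(res.x.sum()),
        growth=g,
    )


def turnovers(model: MetabolicModel, fluxes: Mapping[str, float]) -> dict[str, float]:
    """Per-metabolite turnover τ_i = ½ Σ_j |S_ij| |v_j| (tight flux split)."""
    tau = {m.id: 0.0 for m in model.metabolites}
    for r in model.reactions:
        v = abs(float(fluxes.get(r.id, 0.0)))
        if v == 0.0:
            continue
        for mid, coef in r.stoichiometry.items():
            tau[mid] += 0.5 * abs(coef) * v
    return tau


def reference_state(
    model: MetabolicModel,
    condition: Optional[Condition] = None,
    min_growth: float = 1e-9,
) -> ReferenceState:
    """Wildtype baseline: pFBA fluxes w and the turnovers τ derived from w.

    Raises if the wildtype is infeasible or its growth is not positive —
    a perturbation analysis needs a growing baseline.
    """
    if condition is not None:
        model = apply_condition(model, condition)
    sol = pfba(model)
    if not sol.optimal:
        raise SolverError(f"wildtype model {model.id!r} is {sol.status}; no reference state")
    if sol.objective_value <= min_growth:
        raise SolverError(
            f"wildtype growth {sol.objective_value:.3g} is not positive; no reference state"
        )
    return ReferenceState(
        fluxes=dict(sol.fluxes),
        turnovers=turnovers(model, sol.fluxes),
        condition_name=condition.name if condition is not None else "",
        growth=sol.objective_value,
    )


def lmoma(model: MetabolicModel, reference: ReferenceState) -> FluxSolution:
    """Linear MOMA: minimise Σ_j |v_j − w_j| under the perturbed bounds.

    Variables are v plus deviation splits δ⁺, δ⁻ ≥ 0 with
    v_j − w_j = δ_j⁺ − δ_j⁻.  Growth is not constrained — the predicted
    mutant growth is read off the solution.  ``objective_value`` is the
    minimised distance.
    """
    if model.infeasible_marker:
        return _empty(model, "lmoma", "infeasible")
    rids = model.reaction_ids()
    n = len(rids)
    missing = [rid for rid in rids if rid not in reference.fluxes]
    if missing:
        raise KeyError(f"reference lacks fluxes for reactions {missing[:3]}")
    S = stoichiometric_matrix(model)
    m = S.shape[0]
    lb, ub = _bounds(model)
    w = np.array([reference.fluxes[rid] for rid in rids])
    # variables: [v (n), δ⁺ (n), δ⁻ (n)]
    I = sparse.identity(n, format="csr")
    Z = sparse.csr_matrix((m, n))
    A_eq = sparse.vstack(
        [sparse.hstack([S, Z, Z]), sparse.hstack([I, -I, I])]
    ).tocsr()
    b_eq = np.concatenate([np.zeros(m), w])
    c = np.concatenate([np.zeros(n), np.ones(2 * n)])
    bounds = list(zip(lb, ub)) + [(0.0, None)] * (2 * n)
    res = _solve(c, None, None, A_eq, b_eq, bounds)
    status = _status(res)
    if status != "optimal":
        return _empty(model, "lmoma", status)
    v = res.x[:n]
    fluxes = dict(zip(rids, map(float, v)))
    g = fluxes.get(model.objective_reaction)
    return FluxSolution(
        fluxes=fluxes,
        objective_value=_clamp_distance(res.fun),
        status="optimal",
        method="lmoma",
        growth=g,
    )


def mimbl(model: MetabolicModel, reference: ReferenceState) -> FluxSolution:
    """MiMBL: minimise Σ_i |t_i − τ_i| over metabolite turnovers.

    The mutant turnover t_i = ½ Σ_j |S_ij| (v_j⁺ + v_j⁻) is linear in the
    split fluxes, so the whole problem stays an LP.  Because the split is
    not forced tight, the optimiser may loosen a split (v⁺, v⁻ both
    positive) to raise a turnover toward τ_i; minimisation keeps this in
    check and the unperturbed identity (objective exactly 0 when the
    reference is feasible) still holds.
    """
    if model.infeasible_marker:
        return _empty(model, "mimbl", "infeasible")
    rids = model.reaction_ids()
    n = len(rids)
    missing = [rid for rid in rids if rid not in reference.fluxes]
    if missing:
        raise KeyError(f"reference lacks fluxes for reactions {missing[:3]}")
    S = stoichiometric_matrix(model)
    m = S.shape[0]
    mids = model.metabolite_ids()
    tau = np.array([reference.turnovers.get(mid, 0.0) for mid in mids])
    lb, ub = _bounds(model)
    up, um = _split_bounds(lb, ub)
    absS = abs(S)
    # variables: [v⁺ (n), v⁻ (n), ε⁺ (m), ε⁻ (m)]
    Zm = sparse.csr_matrix((m, m))
    Im = sparse.identity(m, format="csr")
    steady = sparse.hstack([S, -S, Zm, Zm])
    turn = sparse.hstack([0.5 * absS, 0.5 * absS, -Im, Im])
    A_eq = sparse.vstack([steady, turn]).tocsr()
    b_eq = np.concatenate([np.zeros(m), tau])
    c = np.concatenate([np.zeros(2 * n), np.ones(2 * m)])
    width = 2 * n + 2 * m
    A_ub, b_ub = _forced_rows(n, lb, ub, 0, n, width)
    bounds = (
        [(0.0, u) for u in up]
        + [(0.0, u) for u in um]
        + [(0.0, None)] * (2 * m)
    )
    res = _solve(c, A_ub, b_ub, A_eq, b_eq, bounds)
    status = _status(res)
    if status != "optimal":
        return _empty(model, "mimbl", status)
    v = res.x[:n] - res.x[n : 2 * n]
    fluxes = dict(zip(rids, map(float, v)))
    g = fluxes.get(model.objective_reaction)
    return FluxSolution(
        fluxes=fluxes,
        objective_value=_clamp_distance(res.fun),
        status="optimal",
        method="mimbl",
        growth=g,
    )


def feasibility_audit(
    model: MetabolicModel, solution: FluxSolution, tol: float = 1e-6
) -> dict[str, float]:
    """Worst steady-state residual and bound violation of an optimal solution.

    Returns ``{"steady_state": |S·v|_∞, "bounds": max violation}``; both
    should be ≤ ``tol`` for any solution this package reports as optimal.
    """
    S = stoichiometric_matrix(model)
    rids = model.reaction_ids()
    v = np.array([solution.fluxes[rid] for rid in rids])
    resid = float(np.abs(S @ v).max()) if len(v) else 0.0
    lb, ub = _bounds(model)
    bviol = float(np.maximum(np.maximum(lb - v, v - ub), 0.0).max()) if len(v) else 0.0
    return {"steady_state": resid, "bounds": bviol}
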