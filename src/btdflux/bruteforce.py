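"""Independent reference implementations used only for validation.

Each function here rebuilds the corresponding linear program *from
scratch* — dense matrices, a different variable layout, equality instead
of inequality encodings where possible, and the HiGHS interior-point
algorithm rather than the dual simplex the main module uses.  They share
no code with :mod:`btdflux.simulate`; tests compare the two routes on
small fixtures.  Never call these for production work: they densify the
problem and scale badly.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel
from .simulate import ReferenceState

__all__ = ["oracle_fba", "oracle_pfba", "oracle_lmoma", "oracle_mimbl"]

_METHOD = "highs-ipm"


def _dense(model: MetabolicModel):
    mids = model.metabolite_ids()
    rids = model.reaction_ids()
    midx = {m: i for i, m in enumerate(mids)}
    S = np.zeros((len(mids), len(rids)))
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            S[midx[mid], j] = coef
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return S, lb, ub, rids


def oracle_fba(model: MetabolicModel, objective: Optional[str] = None):
    """Maximal objective flux by a dense interior-point LP.

    Returns ``(value, fluxes)`` or ``(None, None)`` if not optimal.
    """
    S, lb, ub, rids = _dense(model)
    obj = objective or model.objective_reaction
    c = np.zeros(len(rids))
    c[rids.index(obj)] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method=_METHOD)
    if res.status != 0:
        return None, None
    return -res.fun, dict(zip(rids, map(float, res.x)))


def oracle_pfba(model: MetabolicModel, objective: Optional[str] = None):
    """Two-stage parsimonious FBA with the growth pinned by an equality row.

    Returns ``(growth, total_flux, fluxes)``.
    """
    z, _ = oracle_fba(model, objective)
    if z is None:
        return None, None, None
    S, lb, ub, rids = _dense(model)
    n = len(rids)
    obj = objective or model.objective_reaction
    jobj = rids.index(obj)
    # variables [v (n), a (n)] with a_j >= |v_j| via two inequality rows
    m = S.shape[0]
    A_eq = np.hstack([S, np.zeros((m, n))])
    growth = np.zeros(2 * n)
    growth[jobj] = 1.0
    A_eq = np.vstack([A_eq, growth])
    b_eq = np.concatenate([np.zeros(m), [z]])
    A_ub = np.vstack([
        np.hstack([np.eye(n), -np.eye(n)]),    # v - a <= 0
        np.hstack([-np.eye(n), -np.eye(n)]),   # -v - a <= 0
    ])
    b_ub = np.zeros(2 * n)
    c = np.concatenate([np.zeros(n), np.ones(n)])
    bounds = list(zip(lb, ub)) + [(0.0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method=_METHOD)
    if res.status != 0:
        # the exact growth pin can be marginally infeasible at ipm tolerance
        b_eq[-1] = z * (1 - 1e-9) if z > 0 else z
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=bounds, method=_METHOD)
        if res.status != 0:
            return None, None, None
    v = res.x[:n]
    return float(v[jobj]), float(res.fun), dict(zip(rids, map(float, v)))


def oracle_lmoma(model: MetabolicModel, reference: ReferenceState):
    """Minimal Σ|v − w| by the |·| ≤ auxiliary-variable encoding.

    Returns ``(distance, fluxes)``.
    """
    S, lb, ub, rids = _dense(model)
    n = len(rids)
    m = S.shape[0]
    w = np.array([reference.fluxes[rid] for rid in rids])
    # variables [v (n), a (n)], a_j >= |v_j - w_j|
    A_eq = np.hstack([S, np.zeros((m, n))])
    b_eq = np.zeros(m)
    A_ub = np.vstack([
        np.hstack([np.eye(n), -np.eye(n)]),
        np.hstack([-np.eye(n), -np.eye(n)]),
    ])
    b_ub = np.concatenate([w, -w])
    c = np.concatenate([np.zeros(n), np.ones(n)])
    bounds = list(zip(lb, ub)) + [(0.0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method=_METHOD)
    if res.status != 0:
        return None, None
    return float(res.fun), dict(zip(rids, map(float, res.x[:n])))


def oracle_mimbl(model: MetabolicModel, reference: ReferenceState):
    """Minimal Σ|t_i − τ_i| over turnovers, dense encoding.

    Variables are split fluxes (p, q) with v = p − q and per-metabolite
    deviation magnitudes a_i ≥ |t_i − τ_i| where
    t_i = ½ Σ_j |S_ij| (p_j + q_j).  Returns ``(distance, fluxes)``.
    """
    S, lb, ub, rids = _dense(model)
    n = len(rids)
    m = S.shape[0]
    mids = model.metabolite_ids()
    tau = np.array([reference.turnovers.get(mid, 0.0) for mid in mids])
    H = 0.5 * np.abs(S)
    # variables [p (n), q (n), a (m)]
    A_eq = np.hstack([S, -S, np.zeros((m, m))])
    b_eq = np.zeros(m)
    A_ub_rows = [
        np.hstack([H, H, -np.eye(m)]),     # t - a <= tau
        np.hstack([-H, -H, -np.eye(m)]),   # -t - a <= -tau
    ]
    b_ub = np.concatenate([tau, -tau])
    # forced one-signed bounds on v = p - q
    extra, extra_rhs = [], []
    for j in range(n):
        if lb[j] > 0:
            row = np.zeros(2 * n + m)
            row[j], row[n + j] = -1.0, 1.0
            extra.append(row)
            extra_rhs.append(-lb[j])
        if ub[j] < 0:
            row = np.zeros(2 * n + m)
            row[j], row[n + j] = 1.0, -1.0
            extra.append(row)
            extra_rhs.append(ub[j])
    A_ub = np.vstack(A_ub_rows + ([np.vstack(extra)] if extra else []))
    if extra:
        b_ub = np.concatenate([b_ub, extra_rhs])
    c = np.concatenate([np.zeros(2 * n), np.ones(m)])
    bounds = (
        [(0.0, max(u, 0.0)) for u in ub]
        + [(0.0, max(-l, 0.0)) for l in lb]
        + [(0.0, None)] * m
    )
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method=_METHOD)
    if res.status != 0:
        return None, None
    v = res.x[:n] - res.x[n : 2 * n]
    return float(res.fun), dict(zip(rids, map(float, v)))
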