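"""Independent oracles used to cross-check the package's solvers.

LPs are re-solved with GLPK through optlang (a code path fully disjoint
from the scipy/HiGHS implementation), convex QPs with scipy's
trust-constr interior-point method (disjoint from OSQP), and tiny routing
problems by brute-force enumeration of route splits. Nothing here imports
the package's own optimization code paths beyond the problem data.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import LinearConstraint, minimize

_INF = float("inf")


def glpk_lp(c, A_ub, b_ub, A_eq, b_eq, lo, hi):
    """Minimize c'x over the polyhedron with GLPK; returns (objective, x)."""
    from optlang.glpk_interface import Constraint, Model, Objective, Variable

    n = len(c)
    xs = [
        Variable(
            f"x{i}",
            lb=None if lo[i] == -_INF else float(lo[i]),
            ub=None if hi[i] == _INF else float(hi[i]),
        )
        for i in range(n)
    ]
    cons = []
    for A, b, eq in ((A_ub, b_ub, False), (A_eq, b_eq, True)):
        for row, rhs in zip(np.atleast_2d(A), np.atleast_1d(b)):
            if not len(row):
                continue
            expr = sum(float(v) * xs[i] for i, v in enumerate(row) if v != 0)
            cons.append(
                Constraint(expr, ub=float(rhs), lb=float(rhs) if eq else None)
            )
    m = Model()
    m.add(cons)
    m.objective = Objective(
        sum(float(ci) * xs[i] for i, ci in enumerate(c) if ci != 0),
        direction="min",
    )
    status = m.optimize()
    if status != "optimal":
        return None, None
    return float(m.objective.value), np.array([v.primal for v in xs])


def trustconstr_qp(P, q, const, A_ub, b_ub, A_eq, b_eq, lo, hi, x0=None):
    """Minimize 0.5 x'Px + q'x + const with scipy trust-constr."""
    n = len(q)
    P = np.asarray(P, float)
    cons = []
    if np.size(A_eq):
        cons.append(LinearConstraint(A_eq, b_eq, b_eq))
    if np.size(A_ub):
        cons.append(LinearConstraint(A_ub, -np.inf, b_ub))
    if x0 is None:
        x0 = np.clip(np.zeros(n), lo, np.where(np.isfinite(hi), hi, 0.0))
    res = minimize(
        lambda x: 0.5 * x @ P @ x + q @ x + const,
        x0,
        jac=lambda x: P @ x + q,
        hess=lambda x: P,
        bounds=np.column_stack([lo, hi]),
        constraints=cons,
        method="trust-constr",
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 20000},
    )
    return float(res.fun), res.x


def brute_force_two_route_min_enzyme(
    mu, yields, kcats_per_route, chain_inv_kcat, caps, steps=2000
):
    """Enumerate splits of biomass production between two routes.

    Returns the minimal total enzyme sum over a grid of splits: biomass
    share a from route 1, (1-a) from route 2; route flux = share*mu/yield
    capped by ``caps``; chain carries the summed route flux.
    """
    best = math.inf
    for a in np.linspace(0.0, 1.0, steps + 1):
        v1 = a * mu / yields[0]
        v2 = (1 - a) * mu / yields[1]
        if v1 > caps[0] + 1e-12 or v2 > caps[1] + 1e-12:
            continue
        total = v1 * sum(kcats_per_route[0]) + v2 * sum(kcats_per_route[1])
        total += (v1 + v2) * chain_inv_kcat
        best = min(best, total)
    return best


def exact_rank_sum_p(a, b):
    """Two-sided Wilcoxon rank-sum p-value by full enumeration."""
    a, b = list(a), list(b)
    pooled = a + b
    n = len(a)
    rank_list = sorted(range(len(pooled)), key=lambda i: pooled[i])
    rank_of = [0] * len(pooled)
    for r, i in enumerate(rank_list, start=1):
        rank_of[i] = r
    observed = sum(rank_of[i] for i in range(n))
    stats = [
        sum(rank_of[i] for i in combo)
        for combo in itertools.combinations(range(len(pooled)), n)
    ]
    mean = np.mean(stats)
    extreme = sum(
        1 for s in stats if abs(s - mean) >= abs(observed - mean) - 1e-12
    )
    return extreme / len(stats)
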