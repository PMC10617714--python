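"""Low-level LP/QP machinery shared by all solvers.

Every optimization problem in this package lives over the variable vector
``x = [v, E, aux...]`` where ``v`` are reaction fluxes and ``E`` per-enzyme
abundances. :class:`Region` assembles the common feasible set

    S v = 0
    lb <= v <= ub
    sum_j v_j / kcat_ij <= E_i   for every enzyme i
    sum_i E_i  (= or <=)  E_tot
    0 <= E_i <= (measured upper bound, if any)

LPs are solved with HiGHS through :func:`scipy.optimize.linprog`; convex
QPs with OSQP at tight tolerances plus solution polishing. Matrices are
dense: the package targets toy- to small-scale models where clarity beats
sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import EnzymeConstrainedModel, InfeasibleModelError, ModelStructureError

__all__ = ["Region", "LPResult", "solve_lp", "solve_qp", "max_growth"]

_INF = float("inf")


@dataclass
class Region:
    """Common feasible region over ``x = [v, E]``."""

    model: EnzymeConstrainedModel
    A_ub: np.ndarray
    b_ub: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    @property
    def n_v(self) -> int:
        return self.model.n_reactions

    @property
    def n_e(self) -> int:
        return self.model.n_enzymes

    @property
    def n_x(self) -> int:
        return self.n_v + self.n_e

    def v_index(self, rxn_id: str) -> int:
        return self.model.reaction_ids.index(rxn_id)

    def e_index(self, enzyme_id: str) -> int:
        return self.n_v + self.model.enzyme_ids.index(enzyme_id)


def build_region(
    model: EnzymeConstrainedModel,
    *,
    enzyme_ub: dict | None = None,
    pool: str | None = "le",
    pool_total: float | None = None,
) -> Region:
    """Assemble the shared constraint set.

    ``pool`` selects how the enzyme pool total enters: ``"le"`` (capacity
    bound, the GECKO pool-exchange reading), ``"eq"`` (the pool is fully
    allocated), or ``None`` (no pool constraint). ``enzyme_ub`` holds
    measured per-enzyme upper bounds (mmol/gDW).
    """
    n_v, n_e = model.n_reactions, model.n_enzymes
    n_x = n_v + n_e

    catalysed = {r for (_, r) in model.kcat}
    for r in catalysed:
        if model.lb[model.reaction_ids.index(r)] < 0:
            raise ModelStructureError(
                f"catalysed reaction {r!r} is reversible; apply "
                "make_irreversible before building capacity constraints"
            )

    A_eq = np.hstack([model.S, np.zeros((model.n_metabolites, n_e))])
    b_eq = np.zeros(model.n_metabolites)

    ub_rows, ub_rhs = [], []
    e_of = {e: i for i, e in enumerate(model.enzyme_ids)}
    r_of = {r: j for j, r in enumerate(model.reaction_ids)}
    coupling: dict[int, np.ndarray] = {}
    for (e, r), k in model.kcat.items():
        i = e_of[e]
        row = coupling.setdefault(i, np.zeros(n_x))
        row[r_of[r]] += 1.0 / k
    for i, row in sorted(coupling.items()):
        row[n_v + i] = -1.0
        ub_rows.append(row)
        ub_rhs.append(0.0)

    total = pool_total if pool_total is not None else model.pool_total
    if pool is not None and total is not None:
        row = np.zeros(n_x)
        row[n_v:] = 1.0
        if pool == "le":
            ub_rows.append(row)
            ub_rhs.append(total)
        elif pool == "eq":
            A_eq = np.vstack([A_eq, row])
            b_eq = np.append(b_eq, total)
        else:
            raise ValueError(f"unknown pool mode {pool!r}")

    lo = np.concatenate([model.lb, np.zeros(n_e)])
    hi = np.concatenate([model.ub, np.full(n_e, _INF)])
    if enzyme_ub:
        for e, b in enzyme_ub.items():
            if e in e_of:
                hi[n_v + e_of[e]] = b

    A_ub = np.array(ub_rows) if ub_rows else np.zeros((0, n_x))
    return Region(model, A_ub, np.array(ub_rhs), A_eq, b_eq, lo, hi)


@dataclass
class LPResult:
    x: np.ndarray
    objective: float
    status: str  # optimal | infeasible | numeric_failure
    # dual values of the variable upper bounds (HiGHS reduced costs); used
    # by proteomics flexibilization to rank limiting enzyme constraints
    upper_duals: np.ndarray | None = None


def solve_lp(
    c: np.ndarray,
    A_ub: np.ndarray,
    b_ub: np.ndarray,
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
) -> LPResult:
    kwargs = dict(
        A_ub=A_ub if A_ub.size else None,
        b_ub=b_ub if A_ub.size else None,
        A_eq=A_eq if A_eq.size else None,
        b_eq=b_eq if A_eq.size else None,
        bounds=np.column_stack([lo, hi]),
        method="highs",
    )
    res = linprog(c, **kwargs)
    if res.status == 2:
        # enzyme abundances sit many orders of magnitude below fluxes;
        # presolve can misjudge such columns as infeasible — recheck
        res = linprog(c, **kwargs, options={"presolve": False})
    if res.status == 0:
        duals = res.upper.marginals if res.upper is not None else None
        return LPResult(res.x, float(res.fun), "optimal", duals)
    if res.status == 2:
        return LPResult(np.full(len(c), np.nan), np.nan, "infeasible")
    return LPResult(np.full(len(c), np.nan), np.nan, "numeric_failure")


def solve_qp(
    P: np.ndarray,
    q: np.ndarray,
    A_ub: np.ndarray,
    b_ub: np.ndarray,
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
) -> LPResult:
    """Minimize ``0.5 x'Px + q'x`` over the given polyhedron (OSQP)."""
    import osqp

    n = len(q)
    blocks, l, u = [], [], []
    if A_eq.size:
        blocks.append(A_eq)
        l.append(b_eq)
        u.append(b_eq)
    if A_ub.size:
        blocks.append(A_ub)
        l.append(np.full(len(b_ub), -_INF))
        u.append(b_ub)
    blocks.append(np.eye(n))
    l.append(lo)
    u.append(hi)
    A = sp.csc_matrix(np.vstack(blocks))
    l = np.concatenate(l)
    u = np.concatenate(u)

    prob = osqp.OSQP()
    prob.setup(
        P=sp.csc_matrix(P),
        q=q,
        A=A,
        l=l,
        u=u,
        verbose=False,
        eps_abs=1e-10,
        eps_rel=1e-10,
        max_iter=200_000,
        polishing=True,
        scaled_termination=False,
    )
    res = prob.solve(raise_error=False)
    status = res.info.status.lower()
    if "solved" in status:
        x = np.asarray(res.x)
        return LPResult(x, float(0.5 * x @ P @ x + q @ x), "optimal")
    if "infeasible" in status:
        return LPResult(np.full(n, np.nan), np.nan, "infeasible")
    return LPResult(np.full(n, np.nan), np.nan, "numeric_failure")


def max_growth(
    model: EnzymeConstrainedModel,
    *,
    enzyme_ub: dict | None = None,
    pool_total: float | None = None,
) -> float:
    """Maximum biomass flux (FBA); ``-inf`` if the model is infeasible."""
    res = max_growth_result(model, enzyme_ub=enzyme_ub, pool_total=pool_total)
    return -res.objective if res.status == "optimal" else -_INF


def max_growth_result(
    model: EnzymeConstrainedModel,
    *,
    enzyme_ub: dict | None = None,
    pool_total: float | None = None,
) -> LPResult:
    reg = build_region(model, enzyme_ub=enzyme_ub, pool="le", pool_total=pool_total)
    c = np.zeros(reg.n_x)
    c[reg.v_index(model.biomass_rxn)] = -1.0
    return solve_lp(c, reg.A_ub, reg.b_ub, reg.A_eq, reg.b_eq, reg.lo, reg.hi)
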