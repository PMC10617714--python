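"""Minimal-adjustment enzyme-allocation predictors and benchmark solvers.

Four variants predict the enzyme allocation ``E_s`` of an alternative
growth condition from a reference allocation ``E_ref`` by minimizing a
distance between the two normalized allocations inside the feasible region
of the protein-constrained model:

    LP1:  min || E_ref/E_ref_tot - E_s/E_s_tot ||_1
    QP1:  min || E_ref/E_ref_tot - E_s/E_s_tot ||_2^2
    LP2:  LP1 objective + lam * || v_ref - v_s ||_1
    QP2:  QP1 objective + lam * || v_ref - v_s ||_2^2

subject to steady state (Nv = 0), flux bounds, kcat capacity coupling, the
enzyme pool balance (sum E_s = E_s_tot) and the growth interval encoded in
the biomass bounds. Euclidean distances are implemented squared, the
standard convex-QP form (the minimizer of a pure norm and of its square
coincide for the single-term variants).

Benchmarks: parsimonious FBA (minimize total flux of the irreversible
model), its enzyme-weighted variant (minimize sum of E_i * kcat_ij over
catalysed pairs), and a kcat-only null allocation used as a negative
control in correlation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import EnzymeAllocation, EnzymeConstrainedModel, ModelStructureError
from .optimize import LPResult, build_region, solve_lp, solve_qp

__all__ = [
    "SolveRequest",
    "SolveResult",
    "solve_parrot",
    "solve_pfba",
    "solve_pfba_eskcat",
    "null_allocation",
    "verify_result",
]

VARIANTS = ("LP1", "QP1", "LP2", "QP2")


@dataclass
class SolveRequest:
    """Inputs of one minimal-adjustment prediction.

    ``distance_support`` chooses which enzymes enter the distance:
    ``"reference"`` (only enzymes present in ``E_ref``; enzymes the
    reference proteomics never saw stay free) or ``"zeros"`` (every model
    enzyme, absent ones at reference 0).
    """

    variant: str
    reference: EnzymeAllocation
    e_s_tot: float
    e_ref_tot: float | None = None  # defaults to reference.total
    lam: float = 0.0
    v_ref: dict = field(default_factory=dict)
    distance_support: str = "reference"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")
        if self.e_ref_tot is None:
            self.e_ref_tot = self.reference.total
        if not self.e_ref_tot > 0 or not self.e_s_tot > 0:
            raise ValueError("E_ref_tot and E_s_tot must be > 0")
        if self.lam > 0 and self.variant in ("LP2", "QP2") and not self.v_ref:
            raise ValueError("v_ref is required when lam > 0")


@dataclass
class SolveResult:
    flux: dict
    allocation: EnzymeAllocation
    objective_value: float
    status: str  # optimal | infeasible | numeric_failure
    variant: str
    lam: float = 0.0
    enzyme_distance: float = float("nan")
    flux_distance: float = float("nan")


def _result_from_region(reg, x, model, total, label) -> tuple:
    flux = {r: float(x[j]) for j, r in enumerate(model.reaction_ids)}
    # "+ 0.0" normalizes IEEE negative zeros from the solver
    values = {e: max(float(x[reg.e_index(e)]), 0.0) + 0.0 for e in model.enzyme_ids}
    alloc = EnzymeAllocation(values=values, total=total, label=label)
    return flux, alloc


def solve_parrot(model: EnzymeConstrainedModel, req: SolveRequest) -> SolveResult:
    """Solve one of the four minimal-adjustment variants.

    ``model`` must already carry the alternative condition's bounds (see
    :func:`parrot.model.apply_condition`); the growth interval is read from
    the biomass reaction's bounds. Absolute values are encoded with split
    non-negative auxiliary variables; Euclidean terms as convex quadratics.
    """
    reg = build_region(model, pool="eq", pool_total=req.e_s_tot)
    n_x = reg.n_x
    support = [
        e
        for e in model.enzyme_ids
        if req.distance_support == "zeros" or e in req.reference.values
    ]
    if not support:
        raise ValueError("no reference enzyme maps to a model enzyme")
    r_vec = np.array(
        [req.reference.values.get(e, 0.0) / req.e_ref_tot for e in support]
    )
    e_idx = np.array([reg.e_index(e) for e in support])
    use_flux = req.variant in ("LP2", "QP2") and req.lam > 0
    v_ref = np.array(
        [req.v_ref.get(r, 0.0) for r in model.reaction_ids] if use_flux else []
    )

    if req.variant in ("LP1", "LP2"):
        n_t = len(support)
        n_u = reg.n_v if use_flux else 0
        n_tot = n_x + n_t + n_u
        A_eq = np.hstack([reg.A_eq, np.zeros((reg.A_eq.shape[0], n_t + n_u))])
        rows = [np.hstack([reg.A_ub, np.zeros((reg.A_ub.shape[0], n_t + n_u))])]
        rhs = [reg.b_ub]
        # |r_i - E_i/E_s_tot| <= t_i  (split into two half-planes)
        for k, i in enumerate(e_idx):
            for sgn in (1.0, -1.0):
                row = np.zeros(n_tot)
                row[i] = sgn / req.e_s_tot
                row[n_x + k] = -1.0
                rows.append(row)
                rhs.append(sgn * r_vec[k])
        if use_flux:
            for j in range(reg.n_v):
                for sgn in (1.0, -1.0):
                    row = np.zeros(n_tot)
                    row[j] = sgn
                    row[n_x + n_t + j] = -1.0
                    rows.append(row)
                    rhs.append(sgn * v_ref[j])
        A_ub = np.vstack(rows)
        b_ub = np.concatenate([np.atleast_1d(r) for r in rhs])
        lo = np.concatenate([reg.lo, np.zeros(n_t + n_u)])
        hi = np.concatenate([reg.hi, np.full(n_t + n_u, np.inf)])
        c = np.zeros(n_tot)
        c[n_x : n_x + n_t] = 1.0
        if use_flux:
            c[n_x + n_t :] = req.lam
        res = solve_lp(c, A_ub, b_ub, A_eq, reg.b_eq, lo, hi)
    else:  # QP1 / QP2
        P = np.zeros((n_x, n_x))
        q = np.zeros(n_x)
        P[e_idx, e_idx] = 2.0 / req.e_s_tot**2
        q[e_idx] = -2.0 * r_vec / req.e_s_tot
        if use_flux:
            jj = np.arange(reg.n_v)
            P[jj, jj] += 2.0 * req.lam
            q[jj] += -2.0 * req.lam * v_ref
        res = solve_qp(P, q, reg.A_ub, reg.b_ub, reg.A_eq, reg.b_eq, reg.lo, reg.hi)

    if res.status != "optimal":
        return SolveResult(
            {}, EnzymeAllocation({}, req.e_s_tot), np.nan, res.status,
            req.variant, req.lam,
        )
    x = res.x
    flux, alloc = _result_from_region(
        reg, x, model, req.e_s_tot, f"{req.variant} prediction"
    )
    gaps = r_vec - x[e_idx] / req.e_s_tot
    if req.variant in ("LP1", "LP2"):
        enz_d = float(np.abs(gaps).sum())
        flx_d = (
            float(np.abs(v_ref - x[: reg.n_v]).sum()) if use_flux else float("nan")
        )
    else:
        enz_d = float((gaps**2).sum())
        flx_d = (
            float(((v_ref - x[: reg.n_v]) ** 2).sum()) if use_flux else float("nan")
        )
    obj = enz_d + (req.lam * flx_d if use_flux else 0.0)
    return SolveResult(
        flux, alloc, obj, "optimal", req.variant, req.lam, enz_d, flx_d
    )


def _require_irreversible(model):
    if np.any(model.lb < 0):
        raise ModelStructureError(
            "pFBA-family solvers need an irreversible model; "
            "run make_irreversible first"
        )


def _pin_growth(model, mu, growth_flex):
    m = model.copy()
    if mu is not None:
        j = m.reaction_index(m.biomass_rxn)
        m.lb[j] = mu * (1 - growth_flex)
        m.ub[j] = mu * (1 + growth_flex)
    return m


def _benchmark_result(model, res: LPResult, variant: str) -> SolveResult:
    if res.status != "optimal":
        return SolveResult({}, EnzymeAllocation({}, 0.0), np.nan, res.status, variant)
    n_v = model.n_reactions
    flux = {r: float(res.x[j]) for j, r in enumerate(model.reaction_ids)}
    # minimal enzyme levels supporting the flux: E_i = sum_j v_j / kcat_ij
    values = {e: 0.0 for e in model.enzyme_ids}
    for (e, r), k in model.kcat.items():
        values[e] += max(flux[r], 0.0) / k
    alloc = EnzymeAllocation(
        values=values, total=sum(values.values()), label=f"{variant} minimal levels"
    )
    return SolveResult(flux, alloc, float(res.objective), "optimal", variant)


def solve_pfba(
    model: EnzymeConstrainedModel,
    mu: float | None = None,
    *,
    growth_flex: float = 0.0,
    e_tot: float | None = None,
) -> SolveResult:
    """Parsimonious FBA with enzyme constraints: minimize total flux.

    The model must be irreversible. If ``mu`` is given the biomass flux is
    pinned to ``[mu(1-growth_flex), mu(1+growth_flex)]``, otherwise the
    bounds already on the model are kept. The reported allocation holds the
    minimal enzyme levels supporting the optimal flux.
    """
    _require_irreversible(model)
    m = _pin_growth(model, mu, growth_flex)
    reg = build_region(m, pool="le", pool_total=e_tot)
    c = np.zeros(reg.n_x)
    c[: reg.n_v] = 1.0
    res = solve_lp(c, reg.A_ub, reg.b_ub, reg.A_eq, reg.b_eq, reg.lo, reg.hi)
    if res.status == "optimal":
        res.objective = float(res.x[: reg.n_v].sum())
    return _benchmark_result(m, res, "PFBA")


def solve_pfba_eskcat(
    model: EnzymeConstrainedModel,
    mu: float | None = None,
    *,
    growth_flex: float = 0.0,
    e_tot: float | None = None,
) -> SolveResult:
    """Enzyme-weighted parsimonious benchmark: minimize sum E_i * kcat_ij.

    The objective sums ``E_i * kcat_ij`` over every catalysed
    (enzyme, reaction) pair, i.e. each enzyme is weighted by the sum of its
    turnover numbers. Same constraints as :func:`solve_pfba`.
    """
    _require_irreversible(model)
    m = _pin_growth(model, mu, growth_flex)
    reg = build_region(m, pool="le", pool_total=e_tot)
    c = np.zeros(reg.n_x)
    for (e, _r), k in m.kcat.items():
        c[reg.e_index(e)] += k
    res = solve_lp(c, reg.A_ub, reg.b_ub, reg.A_eq, reg.b_eq, reg.lo, reg.hi)
    out = _benchmark_result(m, res, "ESKCAT")
    if out.status == "optimal":
        # report the allocation actually optimized, not the minimal levels
        values = {
            e: max(float(res.x[reg.e_index(e)]), 0.0) + 0.0 for e in m.enzyme_ids
        }
        out.allocation = EnzymeAllocation(
            values=values, total=sum(values.values()), label="ESKCAT allocation"
        )
        out.objective_value = float(res.objective)
    return out


def null_allocation(
    model: EnzymeConstrainedModel, rule: str = "max"
) -> EnzymeAllocation:
    """kcat-derived pseudo-allocation used as a correlation negative control.

    Each enzyme's "abundance" is a summary of its turnover numbers (h^-1)
    taken verbatim as a value: ``rule`` is ``"max"`` (default), ``"mean"``
    or ``"first"`` for enzymes catalysing several reactions. The result is
    never a feasible solution of the model; it only quantifies how much
    correlation kcat values alone can produce.
    """
    if not model.kcat:
        raise ValueError("model has no kcat entries")
    per_enzyme: dict = {}
    for (e, _r), k in sorted(model.kcat.items()):
        per_enzyme.setdefault(e, []).append(k)
    if rule == "max":
        values = {e: max(ks) for e, ks in per_enzyme.items()}
    elif rule == "mean":
        values = {e: float(np.mean(ks)) for e, ks in per_enzyme.items()}
    elif rule == "first":
        values = {e: ks[0] for e, ks in per_enzyme.items()}
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return EnzymeAllocation(
        values=values, total=sum(values.values()), label=f"kcat null ({rule})"
    )


def verify_result(
    model: EnzymeConstrainedModel,
    result: SolveResult,
    *,
    tol: float = 1e-6,
    check_pool: bool = True,
) -> dict:
    """Check the feasibility contract of an optimal result.

    Returns a dict of relative residuals: steady state, capacity coupling,
    pool balance against the allocation's declared total, and biomass flux
    containment in the model's growth interval. Raises ``AssertionError``
    if any residual exceeds ``tol``.
    """
    if result.status != "optimal":
        raise ValueError("can only verify an optimal result")
    v = np.array([result.flux[r] for r in model.reaction_ids])
    scale = max(1.0, float(np.abs(v).max()))
    steady = float(np.abs(model.S @ v).max()) / scale
    coupling = 0.0
    usage: dict = {}
    for (e, r), k in model.kcat.items():
        usage[e] = usage.get(e, 0.0) + result.flux[r] / k
    for e, u in usage.items():
        gap = u - result.allocation.values.get(e, 0.0)
        coupling = max(coupling, gap / max(1.0, abs(u)))
    s = result.allocation.sum()
    pool = abs(s - result.allocation.total) / max(1.0, result.allocation.total)
    j = model.reaction_index(model.biomass_rxn)
    bio = result.flux[model.biomass_rxn]
    span = max(1.0, abs(model.ub[j]))
    growth = max(model.lb[j] - bio, bio - model.ub[j], 0.0) / span
    residuals = {
        "steady_state": steady,
        "coupling": coupling,
        "pool": pool if check_pool else 0.0,
        "growth": growth,
    }
    bad = {k: r for k, r in residuals.items() if r > tol}
    if bad:
        raise AssertionError(f"feasibility contract violated: {bad}")
    return residuals
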