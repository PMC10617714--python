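"""Synthetic toy protein-constrained models with planted ground truth.

The generator emulates, at desk scale, the setting the predictors are
meant for: a microbe whose metabolism is summarized as a substrate uptake
feeding a linear pathway that fans out into parallel routes toward a
biomass sink, each internal reaction catalysed by its own enzyme with a
log-uniformly sampled turnover number. Three features of real metabolism
are kept because without them every predictor collapses onto the same
answer on a toy network:

* routes differ in biomass yield (as fermentative and respiratory
  pathways do), so route choice propagates into every upstream flux;
* each route has a finite capacity (transport and solvent limits), so
  demand spreads over several routes and measured abundances can bind the
  baseline projection partially instead of being relaxed away;
* every trunk-pathway step is carried by a pair of capacity-limited
  isozymes (as for hexose transporters or alcohol dehydrogenases), so a
  measured bound on one isozyme can stay binding — its partner absorbs
  the spill — instead of limiting growth and being flexibilized away;
* the cell's effective turnover numbers deviate enzyme-specifically from
  the model's nominal kcats (the in vitro / in vivo gap): mostly upward
  (in vivo apparent rates exceed catalogue kcats, which is why measured
  abundances over-constrain such models and need flexibilization) and
  with a spread larger than measurement noise, as reported for apparent
  catalytic rates. Both the bias and the spread default to multiples of
  the measurement-noise sigma, so one knob moves the simulation from an
  ideal model (0) to a realistic mismatch regime.

The planted reference allocation is the enzyme-minimal allocation of the
EFFECTIVE (cell-side) model at the reference growth rate; measurement
noise is lognormal (normal in log10), matching the scale on which
predictions are later scored. At zero noise the effective and nominal
models coincide and every planted state is exactly recoverable.

An alternative condition is derived by perturbing the model (blocking a
route, scaling the uptake bound, or degrading a route's kcats). Its ground
truth comes in two modes: ``aligned`` re-solves the minimal-adjustment
problem from the noise-free reference — the hypothesis the predictors
encode — while ``adversarial`` re-optimizes enzyme allocation from
scratch, probing the failure mode where the cell has no memory of the
reference state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    ConditionConstraints,
    EnzymeAllocation,
    EnzymeConstrainedModel,
    apply_condition,
    make_irreversible,
    net_flux,
)
from .optimize import build_region, max_growth, solve_lp
from .proteomics import ProteomicsTable
from .solvers import SolveRequest, solve_parrot

__all__ = [
    "ToySpec",
    "GroundTruth",
    "SimulatedCondition",
    "GenerationError",
    "generate_toy_pcgem",
    "simulate_condition",
]

PERTURBATIONS = ("block_branch", "scale_uptake", "shift_kcat")


class GenerationError(RuntimeError):
    """The requested toy specification has no feasible growth state."""


@dataclass
class ToySpec:
    """Parameters of one synthetic toy model.

    ``kcat_range`` is sampled log-uniformly, in h^-1; the default spans
    0.1 to 100 s^-1, the bulk of measured turnover numbers.
    ``noise_sigma`` is the standard deviation of measurement noise in
    log10 units (0.2 ~ the fold-change scatter typical of quantitative
    proteomics). The cell's effective turnover numbers are
    ``k_eff = k_nominal * 10^eta`` with ``eta ~ N(bias, spread)`` per
    enzyme; unless set explicitly the spread is ``2.5 * noise_sigma``
    (apparent in vivo rates scatter more than proteomics noise) and the
    bias ``1.75 * noise_sigma`` (catalogue kcats mostly underestimate in
    vivo rates, which is what makes measured abundances over-constrain
    the model). ``capacity_range`` bounds the share of biomass demand one
    route can carry; ``pool_headroom`` scales the enzyme pool above the
    nominal model's minimal demand (the sigma-style pool calibration of
    enzyme-constrained models).
    """

    n_linear: int = 3
    n_branches: int = 4
    reversible_fraction: float = 0.0
    kcat_range: tuple = (3600.0, 36000.0)
    mu_true: float = 0.2
    noise_sigma: float = 0.2
    seed: int = 0
    branch_length_range: tuple = (1, 3)
    yield_range: tuple = (0.4, 1.0)  # biomass per unit route flux
    capacity_range: tuple = (0.3, 0.7)  # route capacity, fraction of demand
    isozyme_capacity_range: tuple = (0.7, 1.3)  # per chain isozyme, x mu_true
    uptake_headroom: float = 3.0  # uptake bound as multiple of mu_true
    pool_headroom: float = 1.5  # pool over the nominal minimal demand
    kcat_error_sigma: float | None = None  # None -> 2.5 * noise_sigma
    kcat_error_bias: float | None = None  # None -> 1.75 * noise_sigma

    def __post_init__(self):
        if self.n_linear < 1:
            raise ValueError("n_linear must be >= 1")
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")
        if not (0 < self.kcat_range[0] <= self.kcat_range[1]):
            raise ValueError("kcat_range must be positive and ordered")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.reversible_fraction <= 1:
            raise ValueError("reversible_fraction must be in [0, 1]")

    @property
    def resolved_kcat_error_sigma(self) -> float:
        return (
            2.5 * self.noise_sigma
            if self.kcat_error_sigma is None
            else self.kcat_error_sigma
        )

    @property
    def resolved_kcat_error_bias(self) -> float:
        return (
            1.75 * self.noise_sigma
            if self.kcat_error_bias is None
            else self.kcat_error_bias
        )


@dataclass
class GroundTruth:
    """Planted flux state and allocation of the reference condition.

    ``true_flux`` and ``true_allocation`` satisfy steady state and kcat
    coupling exactly with respect to the cell's EFFECTIVE turnover
    numbers (``meta['effective_kcat']``); the nominal model's kcats carry
    the planted estimation error and coincide with the effective ones only
    at zero kcat-error spread.
    """

    true_flux: dict
    true_allocation: EnzymeAllocation
    condition: ConditionConstraints
    meta: dict = field(default_factory=dict)  # chain, branches, yields,
    # capacities, uptake_rxn, effective_kcat, kcat_log10_error


@dataclass
class SimulatedCondition:
    """One reference/alternative condition pair with noisy proteomics."""

    model: EnzymeConstrainedModel  # nominal, perturbed, condition-constrained
    cond: ConditionConstraints
    reference_proteomics: ProteomicsTable
    alternative_proteomics: ProteomicsTable
    reference_truth: EnzymeAllocation
    alternative_truth: EnzymeAllocation
    alternative_flux: dict
    perturbation: str = ""
    mode: str = "aligned"


def _min_enzyme_solution(model, mu, *, pool_total=None):
    """min sum(E) at biomass flux pinned to mu; returns (flux, allocation)."""
    m = model.copy()
    j = m.reaction_index(m.biomass_rxn)
    m.lb[j] = m.ub[j] = mu
    split = bool(np.any(m.lb[np.arange(m.n_reactions) != j] < 0))
    work = make_irreversible(m) if split else m
    reg = build_region(work, pool="le", pool_total=pool_total)
    c = np.zeros(reg.n_x)
    c[reg.n_v :] = 1.0
    res = solve_lp(c, reg.A_ub, reg.b_ub, reg.A_eq, reg.b_eq, reg.lo, reg.hi)
    if res.status != "optimal":
        raise GenerationError(f"enzyme-minimal solve failed ({res.status})")
    flux = {r: float(res.x[k]) for k, r in enumerate(work.reaction_ids)}
    if split:
        flux = net_flux(work, flux)
    values = {e: float(res.x[reg.e_index(e)]) for e in work.enzyme_ids}
    alloc = EnzymeAllocation(
        values=values, total=sum(values.values()), label="planted truth"
    )
    return flux, alloc


def _with_kcat(model, kcat):
    m = model.copy()
    m.kcat = dict(kcat)
    return m


def generate_toy_pcgem(spec: ToySpec) -> tuple:
    """Build a toy pcGEM and its planted reference state.

    Topology: EX_substrate -> linear chain -> capacity-limited parallel
    routes of differing yield -> BIOMASS. Every internal reaction carries
    one dedicated enzyme. Deterministic given ``spec.seed``. Returns
    ``(model, truth)`` with the nominal model; the cell-side effective
    kcats live in ``truth.meta``.
    """
    rng = np.random.default_rng(spec.seed)
    mets = [f"M{i}" for i in range(spec.n_linear + 1)]
    reactions = []  # (id, stoich dict, lb, ub)
    kcat, enzymes = {}, []

    def _kcat():
        lo, hi = np.log(spec.kcat_range[0]), np.log(spec.kcat_range[1])
        return float(np.exp(rng.uniform(lo, hi)))

    uptake_ub = spec.uptake_headroom * spec.mu_true
    reactions.append(("EX_substrate", {"M0": 1.0}, 0.0, uptake_ub))

    chain = []
    for i in range(1, spec.n_linear + 1):
        # two capacity-limited isozymes per trunk step
        for tag in ("a", "b"):
            rid, eid = f"R_chain{i}{tag}", f"P_chain{i}{tag}"
            cap = float(rng.uniform(*spec.isozyme_capacity_range) * spec.mu_true)
            reactions.append((rid, {f"M{i - 1}": -1.0, f"M{i}": 1.0}, 0.0, cap))
            enzymes.append(eid)
            kcat[(eid, rid)] = _kcat()
            chain.append(rid)

    mets.append("M_bio")
    hub = f"M{spec.n_linear}"
    branches, yields = [], []
    lo_len, hi_len = spec.branch_length_range
    shares = rng.uniform(*spec.capacity_range, size=spec.n_branches)
    if spec.n_branches == 1:
        shares[:] = np.inf  # a single route must carry the whole demand
    elif shares.sum() < 1.05:
        shares *= 1.05 / shares.sum()  # keep the reference state feasible
    capacities = []
    for b in range(1, spec.n_branches + 1):
        length = int(rng.integers(lo_len, hi_len + 1))
        y = float(rng.uniform(*spec.yield_range))
        cap = float(shares[b - 1] * spec.mu_true / y)
        prev = hub
        path = []
        for k in range(1, length + 1):
            last = k == length
            tgt = "M_bio" if last else f"B{b}_{k}"
            if not last:
                mets.append(tgt)
            rid, eid = f"R_br{b}_{k}", f"P_br{b}_{k}"
            # the route's biomass yield sits on its final step; its
            # capacity (transport/solvent limit) on its first step
            reactions.append(
                (
                    rid,
                    {prev: -1.0, tgt: y if last else 1.0},
                    0.0,
                    cap if k == 1 else np.inf,
                )
            )
            enzymes.append(eid)
            kcat[(eid, rid)] = _kcat()
            path.append(rid)
            prev = tgt
        branches.append(path)
        yields.append(y)
        capacities.append(cap)

    reactions.append(("BIOMASS", {"M_bio": -1.0}, 0.0, np.inf))

    # enzyme-specific in vivo/in vitro gap on turnover numbers
    sigma_k = spec.resolved_kcat_error_sigma
    bias_k = spec.resolved_kcat_error_bias
    eta = {
        e: bias_k + (float(rng.normal(0.0, sigma_k)) if sigma_k > 0 else 0.0)
        for e in enzymes
    }
    effective_kcat = {(e, r): k * 10.0 ** eta[e] for (e, r), k in kcat.items()}

    if spec.reversible_fraction > 0:
        internal = [r for r, *_ in reactions if r not in ("EX_substrate", "BIOMASS")]
        n_rev = int(round(spec.reversible_fraction * len(internal)))
        rev = set(rng.choice(internal, size=n_rev, replace=False)) if n_rev else set()
    else:
        rev = set()

    rids = [r[0] for r in reactions]
    S = np.zeros((len(mets), len(rids)))
    mi = {m: i for i, m in enumerate(mets)}
    lb, ub = [], []
    for j, (rid, stoich, lo_b, hi_b) in enumerate(reactions):
        for m, c in stoich.items():
            S[mi[m], j] = c
        lb.append(-hi_b if rid in rev else lo_b)
        ub.append(hi_b)

    model = EnzymeConstrainedModel(
        metabolite_ids=mets,
        reaction_ids=rids,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        biomass_rxn="BIOMASS",
        enzyme_ids=enzymes,
        kcat=kcat,
    )

    # calibrate capacities: the reference condition supports the observed
    # growth rate by definition, so scale internal capacity limits up if
    # the sampled ones cannot carry it
    g0 = max_growth(
        make_irreversible(model) if bool(np.any(model.lb < 0)) else model
    )
    if g0 <= 0:
        raise GenerationError("sampled topology cannot grow at all")
    if g0 < spec.mu_true:
        factor = 1.02 * spec.mu_true / g0
        for j, rid in enumerate(model.reaction_ids):
            if rid not in ("EX_substrate", "BIOMASS") and np.isfinite(model.ub[j]):
                model.ub[j] *= factor

    flux, alloc = _min_enzyme_solution(
        _with_kcat(model, effective_kcat), spec.mu_true
    )
    if alloc.sum() <= 0:
        raise GenerationError("degenerate spec: zero enzyme demand")
    alloc.total = alloc.sum()
    # pool calibrated against the NOMINAL model's demand (as done when
    # fitting the pool of enzyme-constrained models to observed growth)
    _, nominal_min = _min_enzyme_solution(model, spec.mu_true)
    model.pool_total = spec.pool_headroom * max(nominal_min.sum(), alloc.sum())

    cond = ConditionConstraints(
        mu=spec.mu_true,
        uptake_bounds={"EX_substrate": uptake_ub},
        enzyme_total=model.pool_total,
        label="reference",
    )
    truth = GroundTruth(
        true_flux=flux,
        true_allocation=alloc,
        condition=cond,
        meta={
            "chain": chain,
            "branches": branches,
            "yields": yields,
            "capacities": capacities,
            "uptake_rxn": "EX_substrate",
            "effective_kcat": effective_kcat,
            "kcat_log10_error": eta,
            "pool_headroom": spec.pool_headroom,
        },
    )
    return model, truth


def _noisy_table(alloc, sigma, rng, condition) -> ProteomicsTable:
    records = [
        (e, v * 10 ** rng.normal(0.0, sigma) if v > 0 else 0.0, condition)
        for e, v in sorted(alloc.values.items())
    ]
    return ProteomicsTable.from_records(records, provenance="synthetic")


def _branch_flux(truth, path):
    return abs(truth.true_flux.get(path[0], 0.0))


def simulate_condition(
    model: EnzymeConstrainedModel,
    truth: GroundTruth,
    perturbation: str = "scale_uptake",
    noise_sigma: float | None = None,
    seed: int = 0,
    *,
    mode: str = "aligned",
    factor: float | None = None,
    growth_flex: float = 0.05,
) -> SimulatedCondition:
    """Derive an alternative condition and noisy proteomics for both states.

    Perturbations: ``block_branch`` closes the route carrying the most
    reference flux, ``scale_uptake`` multiplies the uptake bound (default
    factor 0.6), ``shift_kcat`` degrades that route's turnover numbers
    (default factor 0.2, applied to nominal and effective rates alike).
    The alternative ground truth is the cell's minimal-adjustment re-solve
    from the noise-free reference under its effective kinetics
    (``aligned``) or an independent enzyme-minimal re-optimization
    (``adversarial``). The returned model is the nominal perturbed model
    with the alternative condition applied — what a practitioner would
    feed the predictors.
    """
    if perturbation not in PERTURBATIONS:
        raise ValueError(f"perturbation must be one of {PERTURBATIONS}")
    if mode not in ("aligned", "adversarial"):
        raise ValueError("mode must be 'aligned' or 'adversarial'")
    sigma = noise_sigma if noise_sigma is not None else 0.0
    rng = np.random.default_rng(seed)

    ref_table = _noisy_table(truth.true_allocation, sigma, rng, "reference")

    p = model.copy()
    uptake_rxn = truth.meta["uptake_rxn"]
    uptake_ub = truth.condition.uptake_bounds[uptake_rxn]
    shifted = {}
    if perturbation == "block_branch":
        branches = truth.meta["branches"]
        if len(branches) < 2:
            raise GenerationError("block_branch needs at least two routes")
        path = max(branches, key=lambda pth: _branch_flux(truth, pth))
        if _branch_flux(truth, path) <= 0:
            raise GenerationError("no route carries reference flux")
        for rid in path:
            p.ub[p.reaction_index(rid)] = 0.0
    elif perturbation == "scale_uptake":
        f = 0.6 if factor is None else factor
        uptake_ub = uptake_ub * f
        p.ub[p.reaction_index(uptake_rxn)] = uptake_ub
    else:  # shift_kcat
        f = 0.2 if factor is None else factor
        path = max(truth.meta["branches"], key=lambda pth: _branch_flux(truth, pth))
        on_path = set(path)
        shifted = {e for (e, r) in p.kcat if r in on_path}
        p.kcat = {
            (e, r): (k * f if e in shifted else k) for (e, r), k in p.kcat.items()
        }

    eff_kcat = {
        (e, r): (k * (0.2 if factor is None else factor) if e in shifted else k)
        for (e, r), k in truth.meta["effective_kcat"].items()
    }
    p_eff = _with_kcat(p, eff_kcat)

    pool = model.pool_total
    maxg = min(
        max_growth(p_eff, pool_total=pool), max_growth(p, pool_total=pool)
    )
    if not maxg > 0:
        raise GenerationError(f"perturbation {perturbation} kills growth")
    mu_alt = min(truth.condition.mu, maxg * (1 - 1e-9))

    # the cell's alternative-state demand (effective kinetics) and the
    # nominal model's demand; the pool offered to the solvers is
    # calibrated on the latter, as for the reference state
    alt_flux_min, alt_min = _min_enzyme_solution(p_eff, mu_alt, pool_total=pool)
    _, alt_min_nom = _min_enzyme_solution(p, mu_alt, pool_total=pool)
    e_s_tot = truth.meta.get("pool_headroom", 1.0) * max(
        alt_min_nom.sum(), alt_min.sum()
    )

    cond = ConditionConstraints(
        mu=mu_alt,
        uptake_bounds={uptake_rxn: uptake_ub},
        enzyme_total=e_s_tot,
        growth_flex=growth_flex,
        label=f"alternative ({perturbation})",
    )
    constrained_nom, _ = apply_condition(p, cond)
    constrained_eff, _ = apply_condition(p_eff, cond)

    if mode == "aligned":
        req = SolveRequest(
            variant="LP1",
            reference=truth.true_allocation,
            e_s_tot=e_s_tot,
            e_ref_tot=truth.true_allocation.total,
        )
        res = solve_parrot(constrained_eff, req)
        if res.status != "optimal":
            raise GenerationError("aligned ground-truth solve failed")
        alt_alloc, alt_flux = res.allocation, res.flux
    else:
        alt_alloc = EnzymeAllocation(
            values=dict(alt_min.values), total=e_s_tot, label="adversarial truth"
        )
        alt_flux = alt_flux_min

    alt_table = _noisy_table(alt_alloc, sigma, rng, "alternative")

    return SimulatedCondition(
        model=constrained_nom,
        cond=cond,
        reference_proteomics=ref_table,
        alternative_proteomics=alt_table,
        reference_truth=truth.true_allocation,
        alternative_truth=alt_alloc,
        alternative_flux=alt_flux,
        perturbation=perturbation,
        mode=mode,
    )
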