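"""Core data structures for protein-constrained metabolic models.

The canonical in-memory form is explicit: a stoichiometric matrix ``S`` over
true metabolites, flux bounds, and a sparse ``(enzyme, reaction) -> kcat``
map. Enzyme abundances are separate decision variables coupled to fluxes by
capacity constraints

    sum_j v_j / kcat_ij  <=  E_i        (per enzyme i, over its reactions)

which is the explicit re-statement of the GECKO pseudo-metabolite encoding:
complexes (several enzymes on one reaction) each see the full flux, while
isozymes are modelled as separate parallel reactions.

Units: fluxes mmol/gDW/h, abundances mmol/gDW, kcat h^-1, growth h^-1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "EnzymeConstrainedModel",
    "ConditionConstraints",
    "EnzymeAllocation",
    "RelaxationRound",
    "InfeasibleModelError",
    "ModelStructureError",
    "make_irreversible",
    "apply_condition",
    "load_model_json",
    "save_model_json",
    "load_condition_yaml",
    "save_condition_yaml",
]


class ModelStructureError(ValueError):
    """Raised when a model violates its structural invariants."""


class InfeasibleModelError(RuntimeError):
    """Raised when an optimization problem has no feasible point.

    Carries an optional ``relaxation_log`` describing bound-relaxation
    rounds attempted before giving up.
    """

    def __init__(self, message: str, relaxation_log: list | None = None):
        super().__init__(message)
        self.relaxation_log = relaxation_log or []


@dataclass
class EnzymeConstrainedModel:
    """Explicit protein-constrained metabolic model.

    Parameters
    ----------
    metabolite_ids, reaction_ids, enzyme_ids
        Identifier lists; order fixes the row/column layout of ``S``.
    S
        Stoichiometric matrix, ``len(metabolite_ids) x len(reaction_ids)``.
    lb, ub
        Per-reaction flux bounds (mmol/gDW/h).
    biomass_rxn
        Identifier of the biomass pseudo-reaction.
    kcat
        Sparse map ``(enzyme_id, reaction_id) -> turnover number`` (h^-1).
    pool_total
        Optional total enzyme pool E_tot (mmol/gDW).
    enzyme_mw
        Optional molecular weights (g/mmol) for mass-based pool accounting.
    irreversible_map
        Present on models produced by :func:`make_irreversible`; maps each
        reaction id of the split model to ``(original_id, sign)``.
    """

    metabolite_ids: list
    reaction_ids: list
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    biomass_rxn: str
    enzyme_ids: list = field(default_factory=list)
    kcat: dict = field(default_factory=dict)
    pool_total: float | None = None
    enzyme_mw: dict | None = None
    irreversible_map: dict | None = None

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self):
        n_m, n_r = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (n_m, n_r):
            raise ModelStructureError(
                f"S has shape {self.S.shape}, expected ({n_m}, {n_r})"
            )
        if self.lb.shape != (n_r,) or self.ub.shape != (n_r,):
            raise ModelStructureError("lb/ub length must match reaction count")
        if np.any(self.lb > self.ub):
            raise ModelStructureError("lb > ub for some reaction")
        if self.biomass_rxn not in self.reaction_ids:
            raise ModelStructureError(
                f"biomass reaction {self.biomass_rxn!r} not in model"
            )
        enz, rxn = set(self.enzyme_ids), set(self.reaction_ids)
        for (e, r), k in self.kcat.items():
            if not (k > 0) or not math.isfinite(k):
                raise ModelStructureError(f"kcat[{e},{r}] = {k} must be > 0")
            if e not in enz or r not in rxn:
                raise ModelStructureError(f"kcat key ({e}, {r}) references unknown id")

    # -- index helpers ----------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_enzymes(self) -> int:
        return len(self.enzyme_ids)

    @property
    def reversible_flags(self) -> np.ndarray:
        return self.lb < 0

    def reaction_index(self, rxn_id: str) -> int:
        return self.reaction_ids.index(rxn_id)

    def reactions_of_enzyme(self, enzyme_id: str) -> list:
        """``[(reaction_id, kcat), ...]`` for one enzyme."""
        return [(r, k) for (e, r), k in self.kcat.items() if e == enzyme_id]

    def copy(self) -> "EnzymeConstrainedModel":
        return EnzymeConstrainedModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            biomass_rxn=self.biomass_rxn,
            enzyme_ids=list(self.enzyme_ids),
            kcat=dict(self.kcat),
            pool_total=self.pool_total,
            enzyme_mw=dict(self.enzyme_mw) if self.enzyme_mw else None,
            irreversible_map=dict(self.irreversible_map)
            if self.irreversible_map
            else None,
        )


@dataclass
class ConditionConstraints:
    """Physiology of one growth condition.

    ``growth_flex`` turns the growth equality v_bio = mu into the symmetric
    interval ``[mu(1-f), mu(1+f)]``; ``bound_flex_step`` is the fractional
    multiplicative increment used when uptake bounds must be relaxed to make
    the measured growth rate reachable.
    """

    mu: float
    uptake_bounds: dict = field(default_factory=dict)
    protein_content: float | None = None  # g protein / gDW
    enzyme_total: float | None = None  # E_tot, mmol/gDW
    growth_flex: float = 0.05
    bound_flex_step: float = 0.01
    max_flex_rounds: int = 500
    label: str = ""

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError("growth rate mu must be > 0")
        if not 0 <= self.growth_flex < 1:
            raise ValueError("growth_flex must be in [0, 1)")
        if not 0 < self.bound_flex_step <= 1:
            raise ValueError("bound_flex_step must be in (0, 1]")

    @property
    def growth_interval(self) -> tuple:
        return (self.mu * (1 - self.growth_flex), self.mu * (1 + self.growth_flex))


@dataclass
class EnzymeAllocation:
    """Named non-negative per-enzyme abundance vector with a declared total.

    ``total`` is the pool E_tot the allocation was computed against (its sum
    may be strictly below the total when the pool is not exhausted).
    """

    values: dict
    total: float
    label: str = ""

    def __post_init__(self):
        bad = {e: v for e, v in self.values.items() if v < 0}
        if bad:
            raise ValueError(f"negative abundances: {bad}")
        s = self.sum()
        if s > self.total * (1 + 1e-6) + 1e-12:
            raise ValueError(
                f"allocation sum {s} exceeds declared total {self.total}"
            )

    def sum(self) -> float:
        return float(sum(self.values.values()))

    def support(self, floor: float = 1e-12) -> set:
        """Enzymes with abundance above ``floor`` (mmol/gDW)."""
        return {e for e, v in self.values.items() if v > floor}

    def restricted(self, floor: float = 1e-12) -> "EnzymeAllocation":
        vals = {e: v for e, v in self.values.items() if v > floor}
        return EnzymeAllocation(values=vals, total=self.total, label=self.label)


@dataclass
class RelaxationRound:
    """One multiplicative uptake-bound relaxation step."""

    round_index: int
    factor: float  # cumulative multiplier applied to the measured bounds
    max_growth: float  # best reachable growth after this round


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def make_irreversible(model: EnzymeConstrainedModel) -> EnzymeConstrainedModel:
    """Split every reversible reaction into forward/backward halves.

    Both halves inherit the original reaction's kcat entries; a mapping from
    new reaction ids to ``(original_id, sign)`` is stored on the result so
    net fluxes can be recovered. Already-irreversible models come back as a
    copy with an identity mapping.
    """
    new_ids, cols, lb, ub = [], [], [], []
    mapping = {}
    for j, rid in enumerate(model.reaction_ids):
        if model.lb[j] < 0:
            fwd, bwd = rid, rid + "_REV"
            new_ids += [fwd, bwd]
            cols += [model.S[:, j], -model.S[:, j]]
            lb += [0.0, 0.0]
            ub += [max(model.ub[j], 0.0), -model.lb[j]]
            mapping[fwd] = (rid, 1)
            mapping[bwd] = (rid, -1)
        else:
            new_ids.append(rid)
            cols.append(model.S[:, j])
            lb.append(model.lb[j])
            ub.append(model.ub[j])
            mapping[rid] = (rid, 1)
    kcat = {}
    for (e, r), k in model.kcat.items():
        kcat[(e, r)] = k
        if (r + "_REV") in mapping:
            kcat[(e, r + "_REV")] = k
    return EnzymeConstrainedModel(
        metabolite_ids=list(model.metabolite_ids),
        reaction_ids=new_ids,
        S=np.column_stack(cols) if cols else model.S.copy(),
        lb=np.array(lb),
        ub=np.array(ub),
        biomass_rxn=model.biomass_rxn,
        enzyme_ids=list(model.enzyme_ids),
        kcat=kcat,
        pool_total=model.pool_total,
        enzyme_mw=dict(model.enzyme_mw) if model.enzyme_mw else None,
        irreversible_map=mapping,
    )


def net_flux(model: EnzymeConstrainedModel, flux: dict) -> dict:
    """Collapse a split model's flux vector back onto original reaction ids."""
    if model.irreversible_map is None:
        return dict(flux)
    out: dict = {}
    for rid, v in flux.items():
        orig, sign = model.irreversible_map[rid]
        out[orig] = out.get(orig, 0.0) + sign * v
    return out


def apply_condition(
    model: EnzymeConstrainedModel, cond: ConditionConstraints
) -> tuple:
    """Constrain a model to one growth condition.

    Sets the uptake upper bounds, pins the biomass flux to the growth
    interval ``[mu(1-f), mu(1+f)]``, and installs the condition's enzyme
    pool total. If the target growth is unreachable, all measured uptake
    bounds are relaxed multiplicatively by ``bound_flex_step`` per round
    until it is (or ``max_flex_rounds`` is hit, which raises
    :class:`InfeasibleModelError` carrying the relaxation log).

    Returns ``(constrained_model, relaxation_log)`` where the log is a list
    of :class:`RelaxationRound`.
    """
    from .optimize import max_growth  # local import to avoid a cycle

    m = model.copy()
    for rid, bound in cond.uptake_bounds.items():
        if rid not in m.reaction_ids:
            raise ModelStructureError(f"uptake reaction {rid!r} not in model")
        j = m.reaction_index(rid)
        m.ub[j] = bound
    if cond.enzyme_total is not None:
        m.pool_total = cond.enzyme_total
    lo, hi = cond.growth_interval
    j_bio = m.reaction_index(m.biomass_rxn)

    log: list = []
    factor = 1.0
    for round_idx in range(cond.max_flex_rounds + 1):
        trial = m.copy()
        for rid in cond.uptake_bounds:
            j = trial.reaction_index(rid)
            trial.ub[j] = cond.uptake_bounds[rid] * factor
        trial.ub[j_bio] = min(trial.ub[j_bio], hi) if np.isfinite(hi) else trial.ub[j_bio]
        g = max_growth(trial)
        if round_idx > 0:
            log.append(RelaxationRound(round_idx, factor, g))
        if g >= lo - 1e-9:
            trial.lb[j_bio] = lo
            trial.ub[j_bio] = hi
            return trial, log
        factor *= 1.0 + cond.bound_flex_step
    raise InfeasibleModelError(
        f"growth {lo:.4g} unreachable after {cond.max_flex_rounds} relaxation "
        f"rounds (last max growth {g:.4g})",
        relaxation_log=log,
    )


# ---------------------------------------------------------------------------
# native toy-model format (JSON) and condition YAML
# ---------------------------------------------------------------------------


def model_to_dict(model: EnzymeConstrainedModel) -> dict:
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        stoich = {
            model.metabolite_ids[i]: model.S[i, j]
            for i in range(model.n_metabolites)
            if model.S[i, j] != 0
        }
        reactions.append(
            {"id": rid, "lb": model.lb[j], "ub": model.ub[j], "stoich": stoich}
        )
    enzymes = []
    for e in model.enzyme_ids:
        enzymes.append(
            {
                "id": e,
                "mw": (model.enzyme_mw or {}).get(e),
                "kcats": {r: k for (ee, r), k in model.kcat.items() if ee == e},
            }
        )
    return {
        "metabolites": list(model.metabolite_ids),
        "reactions": reactions,
        "enzymes": enzymes,
        "biomass": model.biomass_rxn,
        "pool_total": model.pool_total,
    }


def model_from_dict(d: dict) -> EnzymeConstrainedModel:
    mets = list(d["metabolites"])
    rxns = d["reactions"]
    rids = [r["id"] for r in rxns]
    S = np.zeros((len(mets), len(rids)))
    mi = {m: i for i, m in enumerate(mets)}
    for j, r in enumerate(rxns):
        for m, c in r["stoich"].items():
            S[mi[m], j] = c
    kcat, mw = {}, {}
    eids = []
    for e in d.get("enzymes", []):
        eids.append(e["id"])
        if e.get("mw") is not None:
            mw[e["id"]] = e["mw"]
        for r, k in e.get("kcats", {}).items():
            kcat[(e["id"], r)] = k
    inf = float("inf")
    return EnzymeConstrainedModel(
        metabolite_ids=mets,
        reaction_ids=rids,
        S=S,
        lb=np.array([r["lb"] if r["lb"] is not None else -inf for r in rxns]),
        ub=np.array([r["ub"] if r["ub"] is not None else inf for r in rxns]),
        biomass_rxn=d["biomass"],
        enzyme_ids=eids,
        kcat=kcat,
        pool_total=d.get("pool_total"),
        enzyme_mw=mw or None,
    )


def save_model_json(model: EnzymeConstrainedModel, path):
    def _clean(x):
        if isinstance(x, float) and math.isinf(x):
            return None
        return x

    d = model_to_dict(model)
    for r in d["reactions"]:
        r["lb"], r["ub"] = _clean(r["lb"]), _clean(r["ub"])
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, sort_keys=True)


def load_model_json(path) -> EnzymeConstrainedModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def save_condition_yaml(cond: ConditionConstraints, path):
    d = {
        "mu": cond.mu,
        "uptakes": dict(cond.uptake_bounds),
        "protein_content": cond.protein_content,
        "enzyme_total": cond.enzyme_total,
        "growth_flex": cond.growth_flex,
        "bound_flex_step": cond.bound_flex_step,
        "max_flex_rounds": cond.max_flex_rounds,
        "label": cond.label,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def load_condition_yaml(path) -> ConditionConstraints:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return ConditionConstraints(
        mu=d["mu"],
        uptake_bounds=d.get("uptakes", {}) or {},
        protein_content=d.get("protein_content"),
        enzyme_total=d.get("enzyme_total"),
        growth_flex=d.get("growth_flex", 0.05),
        bound_flex_step=d.get("bound_flex_step", 0.01),
        max_flex_rounds=d.get("max_flex_rounds", 500),
        label=d.get("label", ""),
    )
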