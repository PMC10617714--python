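"""Proteomics integration: reference-state flexibilization and baselines.

Measured protein abundances over-constrain a protein-constrained model:
taken as hard enzyme upper bounds they usually make the measured growth
rate infeasible, because kcat values are in vitro estimates and the model's
enzyme demand is idealized. :func:`flexibilize` resolves this the way
enzyme-constrained modelling toolboxes do — iteratively releasing the
measured bound that most limits growth (ranked by the dual value of the
bound in the growth-maximization LP) until the target growth rate is
reachable — and returns the corrected reference allocation ``E_ref``.

:func:`compute_baseline` builds the comparison baseline for an alternative
condition: the norm-minimal enzyme allocation consistent with the model,
the condition's constraints, and the (flexibilized) measurements taken as
upper bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    ConditionConstraints,
    EnzymeAllocation,
    EnzymeConstrainedModel,
    InfeasibleModelError,
)
from .optimize import build_region, max_growth_result, solve_lp, solve_qp

__all__ = [
    "ProteomicsTable",
    "FlexibilizationReport",
    "flexibilize",
    "compute_baseline",
]

USAGE_FLOOR = 1e-12  # mmol/gDW; below this an enzyme counts as absent

COLUMNS = ["protein_id", "abundance_mmol_per_gDW", "condition"]


@dataclass
class ProteomicsTable:
    """Measured protein abundances (mmol/gDW) for one or more conditions."""

    df: pd.DataFrame
    provenance: str = ""

    @classmethod
    def from_records(cls, records, provenance: str = "") -> "ProteomicsTable":
        """``records``: iterable of (protein_id, abundance, condition)."""
        df = pd.DataFrame(records, columns=COLUMNS)
        return cls._validated(df, provenance)

    @classmethod
    def from_dict(
        cls, values: dict, condition: str, provenance: str = ""
    ) -> "ProteomicsTable":
        recs = [(p, a, condition) for p, a in values.items()]
        return cls.from_records(recs, provenance)

    @classmethod
    def from_tsv(cls, path, provenance: str = "") -> "ProteomicsTable":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in COLUMNS[:2] if c not in df.columns]
        if missing:
            raise ValueError(f"proteomics TSV missing columns {missing}")
        if "condition" not in df.columns:
            df["condition"] = ""
        return cls._validated(df[COLUMNS], provenance or str(path))

    @classmethod
    def _validated(cls, df: pd.DataFrame, provenance: str) -> "ProteomicsTable":
        if (df["abundance_mmol_per_gDW"] < 0).any():
            bad = df[df["abundance_mmol_per_gDW"] < 0]
            raise ValueError(f"negative abundances:\n{bad}")
        # duplicate measurements of a protein within a condition: keep the mean
        df = (
            df.groupby(["condition", "protein_id"], as_index=False, sort=True)[
                "abundance_mmol_per_gDW"
            ]
            .mean()[["protein_id", "abundance_mmol_per_gDW", "condition"]]
            .reset_index(drop=True)
        )
        return cls(df=df, provenance=provenance)

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)

    def conditions(self) -> list:
        return sorted(self.df["condition"].unique())

    def abundances(self, condition: str | None = None) -> dict:
        df = self.df
        if condition is not None:
            df = df[df["condition"] == condition]
        return dict(
            zip(df["protein_id"], df["abundance_mmol_per_gDW"].astype(float))
        )


@dataclass
class FlexibilizedEnzyme:
    enzyme_id: str
    original: float
    relaxed: float
    iteration: int


@dataclass
class FlexibilizationReport:
    """Ordered audit trail of released enzyme bounds.

    ``flux`` is the flux vector of the final growth optimum; it doubles as
    the default reference flux distribution ``v_ref`` for the
    flux-regularized predictor variants.
    """

    entries: list = field(default_factory=list)
    achieved_growth: float = float("nan")
    flux: dict = field(default_factory=dict)
    enzyme_ub: dict = field(default_factory=dict)

    def released_ids(self) -> list:
        return [e.enzyme_id for e in self.entries]


def _usage_per_enzyme(model: EnzymeConstrainedModel, flux: dict) -> dict:
    usage: dict = {}
    for (e, r), k in model.kcat.items():
        usage[e] = usage.get(e, 0.0) + max(flux[r], 0.0) / k
    return usage


def flexibilize(
    model: EnzymeConstrainedModel,
    prot: ProteomicsTable | dict,
    mu_target: float,
    *,
    growth_flex: float = 0.05,
    pool_total: float | None = None,
    condition: str | None = None,
) -> tuple:
    """Relax measured enzyme bounds until ``mu_target`` is reachable.

    Measured enzymes get upper bounds equal to their abundance; unmeasured
    enzymes draw freely from the residual pool. While the growth maximum
    falls short of ``mu_target * (1 - growth_flex)``, the measured bound
    with the largest dual value (shadow price magnitude) is released to
    pool-limited, one enzyme per iteration, ties broken by enzyme id.

    Returns ``(model, e_ref, report)``: the input model (structurally
    unchanged — bounds live in ``report.enzyme_ub``), the corrected
    reference allocation (original values for untouched enzymes, the usage
    at the final optimum for released ones), and the audit report.
    """
    measured_all = (
        prot.abundances(condition) if isinstance(prot, ProteomicsTable) else dict(prot)
    )
    measured = {e: a for e, a in measured_all.items() if e in set(model.enzyme_ids)}
    if not measured:
        raise ValueError("no measured protein maps to a model enzyme")

    # growth maximization must be free to fall short of a pinned biomass
    # lower bound, so the working copy opens it up; it is capped at the
    # measured growth rate so the corrected usages refer to that state
    work = model.copy()
    j_bio = work.reaction_index(work.biomass_rxn)
    work.lb[j_bio] = min(work.lb[j_bio], 0.0)
    work.ub[j_bio] = min(work.ub[j_bio], mu_target)

    enzyme_ub = dict(measured)
    target = mu_target * (1 - growth_flex)
    released: list = []
    for iteration in range(len(measured) + 1):
        res = max_growth_result(work, enzyme_ub=enzyme_ub, pool_total=pool_total)
        if res.status != "optimal":
            raise InfeasibleModelError(
                "growth LP infeasible during flexibilization"
            )
        g = -res.objective
        if g >= target - 1e-9:
            break
        n_v = model.n_reactions
        duals = res.upper_duals[n_v:] if res.upper_duals is not None else None
        candidates = [
            (abs(duals[i]) if duals is not None else 0.0, e)
            for i, e in enumerate(model.enzyme_ids)
            if e in enzyme_ub
        ]
        if not candidates:
            raise InfeasibleModelError(
                f"target growth {mu_target:.4g} unreachable even with all "
                f"enzyme bounds released (max growth {g:.4g})"
            )
        # largest shadow price first; lexicographic enzyme id on ties
        candidates.sort(key=lambda t: (-t[0], t[1]))
        _, victim = candidates[0]
        released.append((victim, iteration))
        del enzyme_ub[victim]
    else:
        raise InfeasibleModelError(
            f"target growth {mu_target:.4g} unreachable even with all "
            "enzyme bounds released"
        )

    flux = {r: float(res.x[j]) for j, r in enumerate(model.reaction_ids)}
    usage = _usage_per_enzyme(model, flux)
    e_ref_values = dict(measured)
    entries = []
    for victim, iteration in released:
        relaxed = max(measured[victim], usage.get(victim, 0.0))
        e_ref_values[victim] = relaxed
        entries.append(
            FlexibilizedEnzyme(victim, measured[victim], relaxed, iteration)
        )
    e_ref = EnzymeAllocation(
        values=e_ref_values,
        total=sum(e_ref_values.values()),
        label="flexibilized reference",
    )
    report = FlexibilizationReport(
        entries=entries,
        achieved_growth=g,
        flux=flux,
        enzyme_ub=enzyme_ub,
    )
    return model, e_ref, report


def compute_baseline(
    model: EnzymeConstrainedModel,
    prot_alt: ProteomicsTable | dict,
    cond: ConditionConstraints | None = None,
    norm: int = 1,
    *,
    e_tot: float | None = None,
    floor: float = USAGE_FLOOR,
    condition: str | None = None,
) -> EnzymeAllocation:
    """Norm-minimal re-projection of measured proteomics through the model.

    The model must already carry the alternative condition's bounds. The
    measurements enter as enzyme upper bounds; when ``cond`` is given they
    are first flexibilized toward ``cond.mu`` so the problem is feasible.
    Solves ``min ||E||_norm`` (norm 1 or 2) subject to steady state, flux
    bounds, kcat coupling, the pool capacity and the growth interval, and
    returns the optimizing allocation restricted to enzymes above
    ``floor``.
    """
    if norm not in (1, 2):
        raise ValueError("norm must be 1 or 2")
    if cond is not None:
        _, _, rep = flexibilize(
            model,
            prot_alt,
            cond.mu,
            growth_flex=cond.growth_flex,
            pool_total=e_tot if e_tot is not None else cond.enzyme_total,
            condition=condition,
        )
        enzyme_ub = rep.enzyme_ub
        if e_tot is None:
            e_tot = cond.enzyme_total
    else:
        measured = (
            prot_alt.abundances(condition)
            if isinstance(prot_alt, ProteomicsTable)
            else dict(prot_alt)
        )
        enzyme_ub = {e: a for e, a in measured.items() if e in set(model.enzyme_ids)}

    reg = build_region(model, enzyme_ub=enzyme_ub, pool="le", pool_total=e_tot)
    if norm == 1:
        c = np.zeros(reg.n_x)
        c[reg.n_v :] = 1.0
        res = solve_lp(c, reg.A_ub, reg.b_ub, reg.A_eq, reg.b_eq, reg.lo, reg.hi)
    else:
        P = np.zeros((reg.n_x, reg.n_x))
        idx = np.arange(reg.n_v, reg.n_x)
        P[idx, idx] = 2.0
        res = solve_qp(
            P, np.zeros(reg.n_x), reg.A_ub, reg.b_ub, reg.A_eq, reg.b_eq,
            reg.lo, reg.hi,
        )
    if res.status != "optimal":
        binding = {
            e: b for e, b in sorted(enzyme_ub.items())
        }
        raise InfeasibleModelError(
            f"baseline projection infeasible (status {res.status}); "
            f"measured upper bounds: {binding}"
        )
    values = {
        e: float(res.x[reg.e_index(e)])
        for e in model.enzyme_ids
        if res.x[reg.e_index(e)] > floor
    }
    total = e_tot if e_tot is not None else sum(values.values())
    return EnzymeAllocation(values=values, total=total, label="baseline")
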