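"""Import/export of the GECKO SBML dialect.

GECKO-style models encode enzyme constraints inside SBML by adding one
pseudo-metabolite per enzyme (id ``prot_<UNIPROT>``), consumed by each
catalysed reaction with stoichiometric coefficient ``-1/kcat``, plus draw
reactions ``draw_prot_<UNIPROT>`` converting a shared ``prot_pool``
pseudo-metabolite (supplied by ``prot_pool_exchange``, whose upper bound
is the total pool) into the enzyme at its molecular weight. The importer
translates this embedding into the package's explicit form — true-
metabolite stoichiometry plus a ``(enzyme, reaction) -> kcat`` map — and
the exporter writes it back, so round trips are lossless.
"""

from __future__ import annotations

import math

import numpy as np

from .model import EnzymeConstrainedModel, ModelStructureError

__all__ = ["import_gecko_sbml", "export_gecko_sbml", "UnsupportedDialectError"]


class UnsupportedDialectError(ModelStructureError):
    """The SBML file uses an enzyme encoding this importer cannot map."""


def _find_biomass(cobra_model, biomass_rxn):
    if biomass_rxn is not None:
        if biomass_rxn not in [r.id for r in cobra_model.reactions]:
            raise ModelStructureError(f"biomass reaction {biomass_rxn!r} not found")
        return biomass_rxn
    for r in cobra_model.reactions:
        if r.objective_coefficient:
            return r.id
    for r in cobra_model.reactions:
        if "biomass" in r.id.lower() or "growth" in r.id.lower():
            return r.id
    raise ModelStructureError(
        "no biomass reaction: none in the objective and no id matching "
        "'biomass'/'growth'"
    )


def import_gecko_sbml(
    path,
    *,
    enzyme_prefix: str = "prot_",
    draw_prefix: str = "draw_prot_",
    pool_exchange: str = "prot_pool_exchange",
    pool_metabolite: str = "prot_pool",
    biomass_rxn: str | None = None,
    kcat_in_per_second: bool = False,
) -> EnzymeConstrainedModel:
    """Read a GECKO-dialect SBML file into the explicit form.

    A coefficient ``-1/k`` of an enzyme pseudo-metabolite in a metabolic
    reaction becomes ``kcat = k`` (h^-1; set ``kcat_in_per_second`` when
    the source encodes ``-1/kcat`` with kcat in s^-1, adding the x3600
    conversion). The pool exchange upper bound becomes ``pool_total``.
    """
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    biomass = _find_biomass(cm, biomass_rxn)

    is_enz = (
        lambda m: m.id.startswith(enzyme_prefix) and m.id != pool_metabolite
    )
    enzyme_mets = [m for m in cm.metabolites if is_enz(m)]
    enzyme_of_met = {m.id: m.id[len(enzyme_prefix) :] for m in enzyme_mets}
    # strip a trailing compartment tag like "[c]" if the id carries one
    enzyme_of_met = {k: v.split("[")[0] for k, v in enzyme_of_met.items()}

    kcat: dict = {}
    mw: dict = {}
    pool_total = None
    keep_rxns = []
    scale = 3600.0 if kcat_in_per_second else 1.0
    for r in cm.reactions:
        if r.id == pool_exchange:
            pool_total = r.upper_bound
            continue
        if r.id.startswith(draw_prefix):
            for m, c in r.metabolites.items():
                if m.id == pool_metabolite and c < 0:
                    enz = r.id[len(draw_prefix) :].split("[")[0]
                    mw[enz] = -c
            continue
        enz_here = {}
        for m, c in r.metabolites.items():
            if m.id == pool_metabolite:
                raise UnsupportedDialectError(
                    f"reaction {r.id!r} touches the pool metabolite directly"
                )
            if m.id in enzyme_of_met:
                if c > 0:
                    raise UnsupportedDialectError(
                        f"enzyme metabolite {m.id!r} produced by non-draw "
                        f"reaction {r.id!r}"
                    )
                enz_here[enzyme_of_met[m.id]] = -c
        for enz, coef in enz_here.items():
            kcat[(enz, r.id)] = scale / coef
        keep_rxns.append(r)

    met_ids = [m.id for m in cm.metabolites if not is_enz(m) and m.id != pool_metabolite]
    mi = {m: i for i, m in enumerate(met_ids)}
    rids = [r.id for r in keep_rxns]
    S = np.zeros((len(met_ids), len(rids)))
    lb, ub = [], []
    for j, r in enumerate(keep_rxns):
        for m, c in r.metabolites.items():
            if m.id in mi:
                S[mi[m.id], j] = c
        lb.append(r.lower_bound)
        ub.append(r.upper_bound)

    enzymes = sorted({e for (e, _r) in kcat} | set(mw))
    return EnzymeConstrainedModel(
        metabolite_ids=met_ids,
        reaction_ids=rids,
        S=S,
        lb=np.array(lb, dtype=float),
        ub=np.array(ub, dtype=float),
        biomass_rxn=biomass,
        enzyme_ids=enzymes,
        kcat=kcat,
        pool_total=pool_total if pool_total is None or math.isfinite(pool_total) else None,
        enzyme_mw=mw or None,
    )


def export_gecko_sbml(
    model: EnzymeConstrainedModel,
    path,
    *,
    enzyme_prefix: str = "prot_",
    draw_prefix: str = "draw_prot_",
    pool_exchange: str = "prot_pool_exchange",
    pool_metabolite: str = "prot_pool",
):
    """Write the explicit model back into the GECKO SBML dialect."""
    import cobra

    cm = cobra.Model("pcgem")
    mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolite_ids}
    enz_mets = {
        e: cobra.Metabolite(enzyme_prefix + e, compartment="c")
        for e in model.enzyme_ids
    }
    pool = cobra.Metabolite(pool_metabolite, compartment="c")
    cm.add_metabolites(list(mets.values()) + list(enz_mets.values()) + [pool])

    big = 1e6  # SBML-safe stand-in for an unbounded flux
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        r = cobra.Reaction(rid)
        lo = float(model.lb[j]) if math.isfinite(model.lb[j]) else -big
        hi = float(model.ub[j]) if math.isfinite(model.ub[j]) else big
        r.lower_bound, r.upper_bound = lo, hi
        stoich = {
            mets[model.metabolite_ids[i]]: float(model.S[i, j])
            for i in range(model.n_metabolites)
            if model.S[i, j] != 0
        }
        r.add_metabolites(stoich)
        rxns.append(r)
    r_of = {rid: r for rid, r in zip(model.reaction_ids, rxns)}
    for (e, rid), k in model.kcat.items():
        r_of[rid].add_metabolites({enz_mets[e]: -1.0 / k})
    for e in model.enzyme_ids:
        d = cobra.Reaction(draw_prefix + e)
        d.lower_bound, d.upper_bound = 0.0, big
        w = (model.enzyme_mw or {}).get(e, 1.0)
        d.add_metabolites({pool: -w, enz_mets[e]: 1.0})
        rxns.append(d)
    px = cobra.Reaction(pool_exchange)
    px.lower_bound = 0.0
    px.upper_bound = model.pool_total if model.pool_total is not None else big
    px.add_metabolites({pool: 1.0})
    rxns.append(px)
    cm.add_reactions(rxns)
    cm.objective = r_of[model.biomass_rxn]
    cobra.io.write_sbml_model(cm, str(path))
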