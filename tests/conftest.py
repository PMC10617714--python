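import numpy as np
import pytest

from parrot import (
    ConditionConstraints,
    EnzymeAllocation,
    EnzymeConstrainedModel,
    ToySpec,
    apply_condition,
    generate_toy_pcgem,
    simulate_condition,
)
from parrot.model import make_irreversible
from parrot.proteomics import flexibilize


def build_model(reactions, kcat, biomass, pool_total=None, enzyme_mw=None):
    """Compact model builder: reactions = [(id, {met: coef}, lb, ub), ...]."""
    mets = sorted({m for _, st, _, _ in reactions for m in st})
    rids = [r[0] for r in reactions]
    S = np.zeros((len(mets), len(rids)))
    mi = {m: i for i, m in enumerate(mets)}
    for j, (_, st, _, _) in enumerate(reactions):
        for m, c in st.items():
            S[mi[m], j] = c
    enzymes = sorted({e for (e, _) in kcat})
    return EnzymeConstrainedModel(
        metabolite_ids=mets,
        reaction_ids=rids,
        S=S,
        lb=np.array([r[2] for r in reactions], float),
        ub=np.array([r[3] for r in reactions], float),
        biomass_rxn=biomass,
        enzyme_ids=enzymes,
        kcat=dict(kcat),
        pool_total=pool_total,
        enzyme_mw=enzyme_mw,
    )


@pytest.fixture
def chain_model():
    """EX -> A -> B -> C -> demand, 3 enzymes, kcats 100/200/400 h^-1."""
    v = 10.0
    rxns = [
        ("EX", {"A": 1.0}, 0.0, v),
        ("R1", {"A": -1.0, "B": 1.0}, 0.0, np.inf),
        ("R2", {"B": -1.0, "C": 1.0}, 0.0, np.inf),
        ("R3", {"C": -1.0, "D": 1.0}, 0.0, np.inf),
        ("DEMAND", {"D": -1.0}, v, v),
    ]
    kc = {("e1", "R1"): 100.0, ("e2", "R2"): 200.0, ("e3", "R3"): 400.0}
    return build_model(rxns, kc, "DEMAND")


@pytest.fixture
def branched_model():
    """Two parallel routes with different kcats toward one sink."""
    rxns = [
        ("EX", {"A": 1.0}, 0.0, 10.0),
        ("RA", {"A": -1.0, "Z": 1.0}, 0.0, np.inf),
        ("RB", {"A": -1.0, "Z": 1.0}, 0.0, np.inf),
        ("BIOMASS", {"Z": -1.0}, 0.0, np.inf),
    ]
    kc = {("ea", "RA"): 100.0, ("eb", "RB"): 400.0}
    return build_model(rxns, kc, "BIOMASS")


def conditioned_cases(n_cases=10):
    """Suite of small condition-constrained problems for oracle checks.

    Each case bundles a condition-constrained toy model with a
    flexibilized reference allocation, reference flux vector and the
    alternative pool total — everything the predictors and benchmarks
    need. Models stay at or below 10 reactions.
    """
    cases = []
    seed = 0
    while len(cases) < n_cases:
        spec = ToySpec(
            n_linear=1,
            n_branches=2,
            branch_length_range=(1, 2),
            noise_sigma=0.15,
            seed=seed,
        )
        seed += 1
        model, truth = generate_toy_pcgem(spec)
        if model.n_reactions > 10:
            continue
        sim = simulate_condition(
            model,
            truth,
            perturbation=("scale_uptake", "block_branch", "shift_kcat")[seed % 3],
            noise_sigma=spec.noise_sigma,
            seed=1000 + seed,
        )
        ref_model, _ = apply_condition(model, truth.condition)
        _, e_ref, rep = flexibilize(
            ref_model,
            sim.reference_proteomics,
            truth.condition.mu,
            growth_flex=truth.condition.growth_flex,
            pool_total=model.pool_total,
            condition="reference",
        )
        cases.append(
            {
                "name": f"toy{seed}",
                "model": sim.model,
                "e_ref": e_ref,
                "v_ref": rep.flux,
                "e_s_tot": sim.cond.enzyme_total,
                "sim": sim,
            }
        )
    return cases


@pytest.fixture(scope="session")
def oracle_cases():
    return conditioned_cases(10)


@pytest.fixture
def identity_case(chain_model):
    """Reference allocation that is feasible under the same constraints."""
    model = chain_model.copy()
    v = 10.0
    e_ref = EnzymeAllocation(
        values={"e1": v / 100.0, "e2": v / 200.0, "e3": v / 400.0},
        total=v / 100.0 + v / 200.0 + v / 400.0,
        label="identity reference",
    )
    return model, e_ref
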