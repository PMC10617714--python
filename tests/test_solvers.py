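import numpy as np
import pytest

from parrot import (
    EnzymeAllocation,
    SolveRequest,
    make_irreversible,
    null_allocation,
    solve_parrot,
    solve_pfba,
    solve_pfba_eskcat,
    verify_result,
)
from parrot.model import ModelStructureError

from conftest import build_model


def test_reference_feasible_gives_zero_distance(identity_case):
    model, e_ref = identity_case
    for variant in ("LP1", "QP1"):
        res = solve_parrot(
            model, SolveRequest(variant=variant, reference=e_ref, e_s_tot=e_ref.total)
        )
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)
        for e, v in e_ref.values.items():
            assert res.allocation.values[e] == pytest.approx(v, rel=1e-6)


def test_lambda_zero_collapses_to_single_objective(identity_case, oracle_cases):
    case = oracle_cases[0]
    for one, two in (("LP1", "LP2"), ("QP1", "QP2")):
        r1 = solve_parrot(
            case["model"],
            SolveRequest(variant=one, reference=case["e_ref"],
                         e_s_tot=case["e_s_tot"]),
        )
        r2 = solve_parrot(
            case["model"],
            SolveRequest(variant=two, reference=case["e_ref"],
                         e_s_tot=case["e_s_tot"], lam=0.0, v_ref=case["v_ref"]),
        )
        assert r2.objective_value == pytest.approx(r1.objective_value, abs=1e-6)
        for e in r1.allocation.values:
            assert r2.allocation.values[e] == pytest.approx(
                r1.allocation.values[e], abs=1e-6 * case["e_s_tot"]
            )


def test_blocked_branch_reallocates_to_open_route(branched_model):
    # reference uses the high-kcat route RB; the alternative condition
    # blocks it, so the predictor must shift the allocation onto RA
    m = branched_model.copy()
    mu = 5.0
    j = m.reaction_index("BIOMASS")
    m.lb[j] = m.ub[j] = mu
    m.ub[m.reaction_index("RB")] = 0.0
    e_ref = EnzymeAllocation(
        values={"ea": 0.0, "eb": mu / 400.0}, total=mu / 400.0
    )
    e_s_tot = mu / 100.0  # exactly what the open route needs
    res = solve_parrot(
        m, SolveRequest(variant="LP1", reference=e_ref, e_s_tot=e_s_tot)
    )
    assert res.status == "optimal"
    assert res.allocation.values["ea"] == pytest.approx(mu / 100.0, rel=1e-6)
    assert res.flux["RA"] == pytest.approx(mu, rel=1e-6)
    # the whole normalized mass moved: distance = |0 - 1| + |1 - 0|
    assert res.objective_value == pytest.approx(2.0, rel=1e-6)


def test_normalization_invariance(oracle_cases):
    case = oracle_cases[1]
    base = solve_parrot(
        case["model"],
        SolveRequest(variant="LP1", reference=case["e_ref"],
                     e_s_tot=case["e_s_tot"]),
    )
    scaled_ref = EnzymeAllocation(
        values={e: 7.0 * v for e, v in case["e_ref"].values.items()},
        total=7.0 * case["e_ref"].total,
    )
    scaled = solve_parrot(
        case["model"],
        SolveRequest(variant="LP1", reference=scaled_ref,
                     e_s_tot=case["e_s_tot"]),
    )
    assert scaled.objective_value == pytest.approx(base.objective_value, abs=1e-9)


class TestPfba:
    def test_forced_chain_objective(self, chain_model):
        res = solve_pfba(make_irreversible(chain_model))
        # demand 10 forces every internal and exchange flux to 10
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(50.0, rel=1e-9)
        assert res.allocation.values["e1"] == pytest.approx(0.1)

    def test_rejects_reversible_model(self):
        m = build_model(
            [("R1", {"A": -1.0, "B": 1.0}, -5.0, 5.0),
             ("BIO", {"B": -1.0}, 0.0, 1.0)],
            {},
            "BIO",
        )
        with pytest.raises(ModelStructureError, match="irreversible"):
            solve_pfba(m)

    def test_picks_minimum_flux_route_ignoring_kcat(self):
        # route A: 1 step, slow enzyme; route B: 2 steps, fast enzymes.
        # minimal total flux prefers the short route regardless of kcat
        mu = 2.0
        rxns = [
            ("EX", {"A": 1.0}, 0.0, 10.0),
            ("RA", {"A": -1.0, "Z": 1.0}, 0.0, np.inf),
            ("RB1", {"A": -1.0, "B": 1.0}, 0.0, np.inf),
            ("RB2", {"B": -1.0, "Z": 1.0}, 0.0, np.inf),
            ("BIOMASS", {"Z": -1.0}, mu, mu),
        ]
        kc = {
            ("slow", "RA"): 10.0,
            ("fast1", "RB1"): 4000.0,
            ("fast2", "RB2"): 4000.0,
        }
        model = build_model(rxns, kc, "BIOMASS")
        res = solve_pfba(model)
        assert res.flux["RA"] == pytest.approx(mu, rel=1e-9)
        assert res.flux["RB1"] == pytest.approx(0.0, abs=1e-9)
        # brute force over splits confirms the optimum
        totals = [
            mu + mu + (a * mu) + 2 * (1 - a) * mu for a in np.linspace(0, 1, 101)
        ]
        assert res.objective_value == pytest.approx(min(totals), rel=1e-9)


class TestEskcat:
    def test_single_enzyme_chain_identity(self, chain_model):
        # with one enzyme per reaction and forced fluxes, minimal E makes
        # E_i * kcat_i = v_i, so the objective equals the total flux over
        # catalysed reactions
        res = solve_pfba_eskcat(make_irreversible(chain_model))
        assert res.objective_value == pytest.approx(30.0, rel=1e-9)

    def test_zero_growth_means_zero_everything(self, chain_model):
        m = chain_model.copy()
        m.ub[m.reaction_index("EX")] = 0.0
        j = m.reaction_index("DEMAND")
        m.lb[j], m.ub[j] = 0.0, 0.0
        res = solve_pfba_eskcat(m)
        assert res.objective_value == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in res.flux.values())
        assert res.allocation.sum() == pytest.approx(0.0, abs=1e-12)

    def test_branched_choice_matches_brute_force(self):
        # eskcat weighs routes by enzyme-capacity cost, which can disagree
        # with pFBA's flux count
        mu = 2.0
        rxns = [
            ("EX", {"A": 1.0}, 0.0, 10.0),
            ("RA", {"A": -1.0, "Z": 1.0}, 0.0, np.inf),
            ("RB1", {"A": -1.0, "B": 1.0}, 0.0, np.inf),
            ("RB2", {"B": -1.0, "Z": 1.0}, 0.0, np.inf),
            ("BIOMASS", {"Z": -1.0}, mu, mu),
        ]
        kc = {
            ("slow", "RA"): 10.0,
            ("fast1", "RB1"): 4000.0,
            ("fast2", "RB2"): 4000.0,
        }
        model = build_model(rxns, kc, "BIOMASS")
        res = solve_pfba_eskcat(model)
        # objective for split a via RA: E*kcat sums to a*mu + 2*(1-a)*mu
        # (identity E_i = v/k), independent of kcat values here; both
        # routes tie except the 2-step route costs twice
        assert res.flux["RA"] == pytest.approx(mu, rel=1e-9)
        assert res.objective_value == pytest.approx(mu, rel=1e-9)


class TestNull:
    def test_rules(self):
        model = build_model(
            [("R1", {"A": -1.0}, 0.0, 1.0), ("R2", {"A": 1.0}, 0.0, 1.0)],
            {("e1", "R1"): 100.0, ("e1", "R2"): 500.0, ("e2", "R2"): 3600.0},
            "R1",
        )
        assert null_allocation(model, "max").values == {"e1": 500.0, "e2": 3600.0}
        assert null_allocation(model, "mean").values["e1"] == pytest.approx(300.0)
        assert null_allocation(model, "first").values["e1"] == 100.0
        with pytest.raises(ValueError):
            null_allocation(model, "median")

    def test_uncorrelated_with_independent_allocation(self):
        # against an allocation drawn independently of kcat, the null's
        # correlation stays weak in the vast majority of draws
        from parrot.evaluation import pair_allocations, pearson

        rng = np.random.default_rng(42)
        n, weak = 50, 0
        draws = 100
        for _ in range(draws):
            kcats = 10 ** rng.uniform(2.0, 5.0, n)
            rxns = [("R0", {"A": 1.0}, 0.0, 1.0)] + [
                (f"R{i+1}", {"A": -1.0}, 0.0, 1.0) for i in range(n)
            ]
            kc = {(f"e{i}", f"R{i+1}"): float(kcats[i]) for i in range(n)}
            model = build_model(rxns, kc, "R0")
            null = null_allocation(model)
            planted = EnzymeAllocation(
                values={f"e{i}": float(10 ** rng.normal(-4, 0.5)) for i in range(n)},
                total=1.0,
            )
            r = pearson(pair_allocations(null, planted))
            weak += abs(r) < 0.5
        assert weak >= 0.9 * draws


def test_feasibility_contract_on_fixture_suite(oracle_cases):
    for case in oracle_cases:
        for variant in ("LP1", "QP1"):
            res = solve_parrot(
                case["model"],
                SolveRequest(variant=variant, reference=case["e_ref"],
                             e_s_tot=case["e_s_tot"]),
            )
            assert res.status == "optimal", case["name"]
            verify_result(case["model"], res, tol=1e-6)
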