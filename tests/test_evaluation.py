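import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parrot import (
    EnzymeAllocation,
    InsufficientOverlapError,
    SolveRequest,
    compare_methods,
    pair_allocations,
    pearson,
    rmdse,
    sweep_lambda,
)
from parrot.evaluation import UndefinedCorrelationError, score_pair

from oracles import exact_rank_sum_p


def _alloc(values):
    return EnzymeAllocation(values=values, total=sum(values.values()) or 1.0)


class TestPairing:
    def test_identical_allocations(self):
        a = _alloc({f"e{i}": float(i + 1) for i in range(5)})
        pv = pair_allocations(a, a)
        assert pv.n_pairs == 5 and pv.n_dropped_zero == 0
        assert np.allclose(pv.x, pv.y)

    def test_disjoint_supports_raise(self):
        a = _alloc({"e1": 1.0, "e2": 2.0})
        b = _alloc({"e3": 1.0, "e4": 2.0})
        with pytest.raises(InsufficientOverlapError):
            pair_allocations(a, b)

    def test_zero_entries_dropped_and_counted(self):
        a = _alloc({"e1": 1.0, "e2": 2.0, "e3": 3.0, "e4": 0.0, "e5": 1.0})
        b = _alloc({"e1": 1.0, "e2": 2.0, "e3": 3.0, "e4": 1.0, "e9": 2.0})
        pv = pair_allocations(a, b)
        assert pv.n_pairs == 3 and pv.n_dropped_zero == 1

    def test_pseudocount_keeps_zero_entries(self):
        a = _alloc({"e1": 1.0, "e2": 0.0, "e3": 3.0})
        b = _alloc({"e1": 1.0, "e2": 1.0, "e3": 3.0})
        pv = pair_allocations(a, b, pseudocount=1e-9)
        assert pv.n_pairs == 3 and pv.n_dropped_zero == 0


class TestPearson:
    def test_perfect_correlation(self):
        a = _alloc({"e1": 1.0, "e2": 10.0, "e3": 100.0})
        assert pearson(pair_allocations(a, a)) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = _alloc({"e1": 1.0, "e2": 10.0, "e3": 100.0})
        b = _alloc({"e1": 100.0, "e2": 10.0, "e3": 1.0})
        assert pearson(pair_allocations(a, b)) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 3.0])
        a = _alloc({f"e{i}": float(10.0 ** v) for i, v in enumerate(x)})
        b = _alloc({f"e{i}": float(10.0 ** v) for i, v in enumerate(y)})
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert pearson(pair_allocations(a, b)) == pytest.approx(expected)

    def test_zero_variance_raises(self):
        a = _alloc({"e1": 1.0, "e2": 1.0})
        b = _alloc({"e1": 1.0, "e2": 2.0})
        with pytest.raises(UndefinedCorrelationError):
            pearson(pair_allocations(a, b))

    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-2.0, 2.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_positive_affine_transform(self, scale, shift):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        y = np.array([1.2, 2.9, 2.5, 4.0])
        a = _alloc({f"e{i}": 10.0 ** v for i, v in enumerate(x)})
        b = _alloc({f"e{i}": 10.0 ** v for i, v in enumerate(y)})
        b_t = _alloc({f"e{i}": 10.0 ** (scale * v + shift) for i, v in enumerate(y)})
        assert pearson(pair_allocations(a, b_t)) == pytest.approx(
            pearson(pair_allocations(a, b)), abs=1e-9
        )


class TestRmdse:
    def test_identical_is_zero(self):
        a = _alloc({"e1": 1.0, "e2": 5.0})
        assert rmdse(pair_allocations(a, a)) == 0.0

    def test_uniform_tenfold_gap_is_one(self):
        a = _alloc({f"e{i}": v for i, v in enumerate((1.0, 2.0, 5.0))})
        b = _alloc({f"e{i}": 10.0 * v for i, v in enumerate((1.0, 2.0, 5.0))})
        assert rmdse(pair_allocations(a, b)) == pytest.approx(1.0)

    def test_hand_computed_median(self):
        gaps = (0.1, 0.3, 0.5)
        a = _alloc({f"e{i}": 1.0 for i in range(3)})
        b = _alloc({f"e{i}": 10.0 ** g for i, g in enumerate(gaps)})
        assert rmdse(pair_allocations(a, b)) == pytest.approx(0.3)

    def test_even_count_uses_midpoint(self):
        gaps = (0.1, 0.2, 0.4, 0.8)
        a = _alloc({f"e{i}": 1.0 for i in range(4)})
        b = _alloc({f"e{i}": 10.0 ** g for i, g in enumerate(gaps)})
        assert rmdse(pair_allocations(a, b)) == pytest.approx(
            np.sqrt((0.2**2 + 0.4**2) / 2)
        )

    def test_depends_only_on_gaps(self):
        a = _alloc({f"e{i}": 10.0 ** v for i, v in enumerate((0.0, 1.0, 2.0))})
        b = _alloc({f"e{i}": 10.0 ** (v + 0.3) for i, v in enumerate((0.0, 1.0, 2.0))})
        shifted_a = _alloc(
            {f"e{i}": 10.0 ** (v + 5) for i, v in enumerate((0.0, 1.0, 2.0))}
        )
        shifted_b = _alloc(
            {f"e{i}": 10.0 ** (v + 5.3) for i, v in enumerate((0.0, 1.0, 2.0))}
        )
        assert rmdse(pair_allocations(a, b)) == pytest.approx(
            rmdse(pair_allocations(shifted_a, shifted_b))
        )


class TestCompareMethods:
    def test_identical_scores_give_p_one(self):
        p = compare_methods({"m1": [0.5, 0.6, 0.7], "m2": [0.5, 0.6, 0.7]})
        assert p[("m1", "m2")] == 1.0

    def test_exact_enumeration_small_samples(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 20.0, 30.0]
        expected = exact_rank_sum_p(a, b)
        p = compare_methods({"m1": a, "m2": b})
        assert p[("m1", "m2")] == pytest.approx(expected)

    def test_three_methods_bonferroni_times_three(self):
        scores = {
            "m1": [1.0, 2.0, 3.0, 4.0],
            "m2": [10.0, 20.0, 30.0, 40.0],
            "m3": [1.5, 2.5, 3.5, 4.5],
        }
        p = compare_methods(scores)
        assert len(p) == 3
        raw = exact_rank_sum_p(scores["m1"], scores["m2"])
        assert p[("m1", "m2")] == pytest.approx(min(1.0, 3 * raw))
        assert all(0 < v <= 1 for v in p.values())

    def test_unequal_condition_sets_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            compare_methods({"m1": [1.0, 2.0, 3.0], "m2": [1.0, 2.0]})


class TestSweepLambda:
    def _setup(self, oracle_cases):
        case = oracle_cases[0]
        req = SolveRequest(
            variant="LP2",
            reference=case["e_ref"],
            e_s_tot=case["e_s_tot"],
            lam=0.0,
            v_ref=case["v_ref"],
        )
        return case, req

    def test_baseline_equal_to_lambda_zero_solution(self, oracle_cases):
        from parrot import solve_parrot

        case, req = self._setup(oracle_cases)
        lam0 = solve_parrot(case["model"], req)
        best, curve = sweep_lambda(
            case["model"], req, lam0.allocation.restricted()
        )
        assert best == 0.0
        assert curve[0]["pearson_r"] == pytest.approx(1.0)

    def test_grid_without_zero_breaks_tie_toward_smallest(self, identity_case):
        # the reference state is feasible: enzyme and flux distances are
        # both zero at every lambda, so the whole grid ties at r = 1 and
        # the tie-break must pick the smallest lambda
        model, e_ref = identity_case
        v = 10.0
        v_ref = {"EX": v, "R1": v, "R2": v, "R3": v, "DEMAND": v}
        req = SolveRequest(
            variant="LP2", reference=e_ref, e_s_tot=e_ref.total,
            lam=0.1, v_ref=v_ref,
        )
        grid = [round(0.1 * i, 10) for i in range(1, 11)]
        best, curve = sweep_lambda(model, req, e_ref, grid=grid)
        assert best == pytest.approx(0.1)
        assert len(curve) == 10
        assert all(c["pearson_r"] == pytest.approx(1.0) for c in curve)

    def test_argmax_matches_exhaustive_rescore(self, oracle_cases):
        case, req = self._setup(oracle_cases)
        baseline = case["sim"].alternative_truth.restricted()
        best, curve = sweep_lambda(case["model"], req, baseline)
        assert len(curve) == 11
        scored = [
            (c["lam"], c["pearson_r"]) for c in curve if c["pearson_r"] is not None
        ]
        top = max(r for _, r in scored)
        assert best == min(l for l, r in scored if r >= top - 1e-12)

    def test_lp1_variant_rejected(self, oracle_cases):
        case, req = self._setup(oracle_cases)
        from dataclasses import replace

        with pytest.raises(ValueError):
            sweep_lambda(
                case["model"], replace(req, variant="LP1"), case["e_ref"]
            )
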