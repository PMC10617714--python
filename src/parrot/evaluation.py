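"""Scoring of predicted enzyme allocations against baselines.

Predictions and baselines are compared on the intersection of their
positive supports after log10 transformation, with Pearson correlation and
the root-median square error (RMdSE) as metrics. Methods are compared
across conditions with pairwise two-sided Wilcoxon rank-sum tests under
Bonferroni correction. The lambda sweep scores the flux-regularized
variants over a weight grid and reports the weight with the highest
correlation to the baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
from scipy import stats

from .model import EnzymeAllocation, EnzymeConstrainedModel, InfeasibleModelError
from .solvers import SolveRequest, solve_parrot

__all__ = [
    "PairedLogVectors",
    "EvaluationReport",
    "InsufficientOverlapError",
    "pair_allocations",
    "pearson",
    "rmdse",
    "compare_methods",
    "sweep_lambda",
    "score_pair",
]

DEFAULT_FLOOR = 1e-12


class InsufficientOverlapError(ValueError):
    """Fewer than two enzymes shared between prediction and baseline."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (zero variance in a vector)."""


@dataclass
class PairedLogVectors:
    """Aligned log10 abundances of two allocations on their shared support."""

    enzyme_ids: list
    x: np.ndarray  # log10 of first allocation
    y: np.ndarray  # log10 of second allocation
    n_pairs: int
    n_dropped_zero: int


def pair_allocations(
    pred: EnzymeAllocation,
    base: EnzymeAllocation,
    floor: float = DEFAULT_FLOOR,
    *,
    pseudocount: float | None = None,
) -> PairedLogVectors:
    """Align two allocations on the intersection of their supports.

    Enzymes present in both allocations but at or below ``floor`` in either
    are dropped (counted in ``n_dropped_zero``) so log10 stays defined.
    With ``pseudocount`` set, such enzymes are kept at ``value +
    pseudocount`` instead — a sensitivity mode, off by default.
    """
    if not floor > 0:
        raise ValueError("floor must be > 0")
    common = sorted(set(pred.values) & set(base.values))
    kept, dropped = [], 0
    for e in common:
        a, b = pred.values[e], base.values[e]
        if a > floor and b > floor:
            kept.append((e, a, b))
        elif pseudocount is not None:
            kept.append((e, a + pseudocount, b + pseudocount))
        else:
            dropped += 1
    if len(kept) < 2:
        raise InsufficientOverlapError(
            f"only {len(kept)} enzymes shared above the usage floor"
        )
    ids = [e for e, _, _ in kept]
    x = np.log10([a for _, a, _ in kept])
    y = np.log10([b for _, _, b in kept])
    return PairedLogVectors(ids, x, y, len(kept), dropped)


def pearson(pv: PairedLogVectors) -> float:
    """Pearson correlation of the paired log10 vectors."""
    if pv.n_pairs < 2:
        raise InsufficientOverlapError("need at least 2 pairs")
    if np.ptp(pv.x) == 0 or np.ptp(pv.y) == 0:
        raise UndefinedCorrelationError("zero variance in a log-vector")
    return float(stats.pearsonr(pv.x, pv.y).statistic)


def rmdse(pv: PairedLogVectors) -> float:
    """Root-median square error: sqrt(median of squared log10 gaps)."""
    return float(np.sqrt(np.median((pv.x - pv.y) ** 2)))


def _rank_sum_p(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    method = "exact" if min(len(a), len(b)) < 10 else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def compare_methods(scores: dict) -> dict:
    """Pairwise Wilcoxon rank-sum tests with Bonferroni correction.

    ``scores`` maps method name -> list of per-condition scores; all lists
    must cover the same conditions (equal length, same order). Returns
    ``{(method_a, method_b): adjusted_p}`` for each unordered pair, the raw
    p multiplied by the number of pairs and capped at 1. Exact p-values for
    groups under 10 observations, normal approximation with continuity
    correction otherwise.
    """
    if len(scores) < 2:
        raise ValueError("need at least two methods")
    lengths = {m: len(v) for m, v in scores.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"methods scored on unequal condition sets: {lengths}")
    n_cond = next(iter(lengths.values()))
    if n_cond < 3:
        raise ValueError("need scores for at least 3 conditions")
    pairs = list(combinations(sorted(scores), 2))
    m = len(pairs)
    return {
        (a, b): min(1.0, _rank_sum_p(scores[a], scores[b]) * m) for a, b in pairs
    }


@dataclass
class EvaluationReport:
    """Per-(condition, method) scores plus pairwise method comparisons."""

    records: list = field(default_factory=list)  # dicts: condition, method,
    # pearson_r, rmdse, n_pairs
    pairwise_p: dict = field(default_factory=dict)

    def scores(self, metric: str = "pearson_r") -> dict:
        out: dict = {}
        for rec in self.records:
            out.setdefault(rec["method"], []).append(rec[metric])
        return out

    def median(self, method: str, metric: str = "pearson_r") -> float:
        vals = [r[metric] for r in self.records if r["method"] == method]
        return float(np.median(vals))

    def mean(self, method: str, metric: str = "pearson_r") -> float:
        vals = [r[metric] for r in self.records if r["method"] == method]
        return float(np.mean(vals))

    def to_dict(self) -> dict:
        return {
            "records": self.records,
            "pairwise_p": {f"{a}|{b}": p for (a, b), p in self.pairwise_p.items()},
        }


def score_pair(
    pred: EnzymeAllocation,
    base: EnzymeAllocation,
    floor: float = DEFAULT_FLOOR,
) -> dict:
    pv = pair_allocations(pred, base, floor)
    return {"pearson_r": pearson(pv), "rmdse": rmdse(pv), "n_pairs": pv.n_pairs}


def build_report(
    predictions: dict, baselines: dict, floor: float = DEFAULT_FLOOR
) -> EvaluationReport:
    """Score ``predictions[method][condition]`` against ``baselines[condition]``.

    Pairwise tests are added when at least two methods share scores on at
    least three conditions.
    """
    records = []
    for method, per_cond in sorted(predictions.items()):
        for condition in sorted(per_cond):
            rec = {"condition": condition, "method": method}
            rec.update(score_pair(per_cond[condition], baselines[condition], floor))
            records.append(rec)
    report = EvaluationReport(records=records)
    scores = report.scores("pearson_r")
    n_cond = {len(v) for v in scores.values()}
    if len(scores) >= 2 and n_cond == {max(n_cond)} and max(n_cond) >= 3:
        report.pairwise_p = compare_methods(scores)
    return report


def sweep_lambda(
    model: EnzymeConstrainedModel,
    req_template: SolveRequest,
    baseline: EnzymeAllocation,
    grid=None,
    floor: float = DEFAULT_FLOOR,
) -> tuple:
    """Score an LP2/QP2 variant over a grid of flux weights.

    Solves the variant at each lambda in ``grid`` (default 0, 0.1, ..., 1),
    computes the Pearson correlation to ``baseline``, and returns
    ``(best_lambda, curve)`` where the curve is a list of
    ``{"lam", "pearson_r", "status"}`` entries. Infeasible points are
    flagged and excluded from the argmax; ties go to the smallest lambda.
    """
    if req_template.variant not in ("LP2", "QP2"):
        raise ValueError("lambda sweep applies to LP2/QP2 only")
    if grid is None:
        grid = [round(0.1 * i, 10) for i in range(11)]
    grid = list(grid)
    if not grid or any(not 0 <= g <= 1 for g in grid):
        raise ValueError("grid must be non-empty with values in [0, 1]")
    curve = []
    best_lam, best_r = None, -math.inf
    for lam in grid:
        req = replace(req_template, lam=lam)
        res = solve_parrot(model, req)
        entry = {"lam": lam, "pearson_r": None, "status": res.status}
        if res.status == "optimal":
            r = pearson(pair_allocations(res.allocation, baseline, floor))
            entry["pearson_r"] = r
            if r > best_r + 1e-12:
                best_lam, best_r = lam, r
        curve.append(entry)
    if best_lam is None:
        raise InfeasibleModelError("no lambda on the grid was feasible")
    return best_lam, curve
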