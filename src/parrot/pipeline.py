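"""End-to-end benchmark: simulate conditions, predict, score.

One benchmark run mirrors the full study design on synthetic models: for
each seed a toy pcGEM is generated, an alternative condition is simulated,
the noisy reference proteomics is flexibilized into ``E_ref``, the noisy
alternative proteomics is re-projected into the baseline, and every
requested method predicts the alternative allocation, scored against the
baseline by log10 Pearson correlation and RMdSE.
"""

from __future__ import annotations

from dataclasses import replace

from .evaluation import EvaluationReport, build_report
from .model import apply_condition, make_irreversible
from .proteomics import compute_baseline, flexibilize
from .solvers import (
    SolveRequest,
    null_allocation,
    solve_parrot,
    solve_pfba,
    solve_pfba_eskcat,
)
from .synthetic import ToySpec, generate_toy_pcgem, simulate_condition

__all__ = ["run_condition", "run_benchmark", "DEFAULT_METHODS"]

DEFAULT_METHODS = ("LP1", "QP1", "PFBA", "ESKCAT", "NULL")


def run_condition(
    spec: ToySpec,
    seed: int,
    *,
    methods=DEFAULT_METHODS,
    perturbation: str = "cycle",
    mode: str = "aligned",
    lam: float = 0.1,
):
    """Simulate one condition pair and predict with every method.

    ``perturbation="cycle"`` rotates through the available perturbation
    types by seed, so a multi-seed benchmark covers nutrient limitation,
    route loss and kinetic degradation alike. Returns
    ``(predictions, baseline, sim, e_ref)`` where ``predictions`` maps
    method name to its predicted :class:`EnzymeAllocation`.
    """
    from .synthetic import PERTURBATIONS

    if perturbation == "cycle":
        perturbation = PERTURBATIONS[seed % len(PERTURBATIONS)]
    model, truth = generate_toy_pcgem(replace(spec, seed=seed))
    sim = simulate_condition(
        model,
        truth,
        perturbation=perturbation,
        noise_sigma=spec.noise_sigma,
        seed=seed + 10_000,
        mode=mode,
    )

    # reference state: integrate noisy reference proteomics at the
    # reference condition, correcting over-constraining measurements
    ref_model, _ = apply_condition(model, truth.condition)
    _, e_ref, flex_report = flexibilize(
        ref_model,
        sim.reference_proteomics,
        truth.condition.mu,
        growth_flex=truth.condition.growth_flex,
        pool_total=model.pool_total,
        condition="reference",
    )

    baseline = compute_baseline(
        sim.model,
        sim.alternative_proteomics,
        sim.cond,
        norm=1,
        e_tot=sim.cond.enzyme_total,
        condition="alternative",
    )

    predictions = {}
    irr = None
    for method in methods:
        if method in ("LP1", "QP1", "LP2", "QP2"):
            req = SolveRequest(
                variant=method,
                reference=e_ref,
                e_s_tot=sim.cond.enzyme_total,
                lam=lam if method in ("LP2", "QP2") else 0.0,
                v_ref=flex_report.flux if method in ("LP2", "QP2") else {},
            )
            res = solve_parrot(sim.model, req)
            predictions[method] = res.allocation
        elif method in ("PFBA", "ESKCAT"):
            if irr is None:
                irr = make_irreversible(sim.model)
            solver = solve_pfba if method == "PFBA" else solve_pfba_eskcat
            res = solver(irr, e_tot=sim.cond.enzyme_total)
            predictions[method] = res.allocation
        elif method == "NULL":
            predictions[method] = null_allocation(sim.model)
        else:
            raise ValueError(f"unknown method {method!r}")
    return predictions, baseline, sim, e_ref


def run_benchmark(
    spec: ToySpec,
    seeds,
    *,
    methods=DEFAULT_METHODS,
    perturbation: str = "cycle",
    mode: str = "aligned",
    lam: float = 0.1,
) -> EvaluationReport:
    """Score every method over many seeded condition pairs."""
    predictions: dict = {m: {} for m in methods}
    baselines: dict = {}
    for seed in seeds:
        preds, baseline, _sim, _eref = run_condition(
            spec,
            seed,
            methods=methods,
            perturbation=perturbation,
            mode=mode,
            lam=lam,
        )
        label = f"seed{seed}"
        baselines[label] = baseline
        for m, alloc in preds.items():
            predictions[m][label] = alloc
    return build_report(predictions, baselines)
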