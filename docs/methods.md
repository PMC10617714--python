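# Methods

## Model form

The canonical in-memory form is explicit: a stoichiometric matrix over
true metabolites, per-reaction flux bounds, and a sparse
`(enzyme, reaction) → kcat` map, with enzyme abundances as separate
decision variables. The GECKO SBML embedding (enzyme pseudo-metabolites
with coefficients −1/kcat, draw and pool pseudo-reactions) is translated
at import and regenerated at export. The explicit form keeps every
objective readable and solver-agnostic; kcats are h⁻¹ internally (s⁻¹
sources are converted by ×3600 at import).

Capacity coupling is per enzyme: `Σ_j v_j / kcat_ij ≤ E_i` over the
reactions an enzyme catalyses. This reproduces GECKO semantics — a
complex's subunits are each consumed by the full reaction flux, and
isozymes are separate parallel reactions. Catalysed reactions must be
irreversible when a capacity-constrained problem is built; reversible
reactions are split (`make_irreversible`), duplicating kcats onto both
directions and keeping a net-flux mapping.

## The optimization family

All problems share the constraint set: steady state, flux bounds, kcat
coupling, the enzyme pool, and the biomass flux confined to
`[μ(1−f), μ(1+f)]`. Published descriptions of growth-rate flexibility do
not fix its sidedness; the symmetric interval is the least-informative
reading and `f` is configurable (default 0.05, i.e. 5%).

* **LP1 / LP2** — Manhattan distances, encoded with split non-negative
  auxiliary variables; solved with HiGHS via `scipy.optimize.linprog`.
* **QP1 / QP2** — squared Euclidean distances (the standard convex-QP
  form; for the single-term variant the minimizer coincides with the
  pure-norm problem), solved with OSQP at `eps_abs = eps_rel = 1e-10`
  with solution polishing.
* **Pool constraint.** The four minimal-adjustment variants use the
  equality `Σ E_s = E_s,tot`: enzymes outside the reference support are
  free and absorb any remainder, so the equality is never artificially
  binding. The baseline and the pFBA-family benchmarks use
  `Σ E ≤ E_tot` — the pool-exchange reading of the GECKO encoding. A
  1-norm baseline under a pool *equality* would have a constant
  objective, which is a strong sign the inequality is the intended
  semantics.
* **E_s,tot is a fixed parameter**, taken from the alternative
  condition's measured protein content. Treating it as a variable would
  make the normalized-distance objective non-convex.
* **Distance support.** The objective sums over enzymes present in
  `E_ref` (measured); model enzymes absent from the reference are
  pool-limited free variables excluded from the distance. Including
  thousands of structural zeros would dominate the objective; a
  configurable `"zeros"` mode includes them with reference 0.
* **Reference flux `v_ref`** for the flux-regularized variants defaults
  to the flux vector of the growth optimum used to build `E_ref`
  (returned by flexibilization).
* **Ties** between alternative optima are not broken; the first solver
  optimum is returned. Determinism holds for a fixed backend and seed,
  not across backends.
* Badly scaled LPs (abundances in 1e-9–1e-4 mmol/gDW against fluxes of
  order 1) can make HiGHS presolve misreport infeasibility; infeasible
  verdicts are re-checked once with presolve disabled.

pFBA minimizes total flux of the irreversible model and reports the
minimal enzyme levels supporting its flux (`E_i = Σ_j v_j / kcat_ij`);
its declared allocation total is that sum, and the feasibility contract
checks allocations against their declared totals. The enzyme-weighted
variant minimizes `Σ E_i · kcat_ij` over catalysed pairs. The null model
assigns each enzyme a summary of its own kcats (max by default; mean and
first-association are available) — by construction never a feasible
state, only a correlation negative control.

## Proteomics integration

Measured abundances become enzyme upper bounds. Because such bounds
usually make the measured growth rate unreachable, `flexibilize`
iteratively releases the measured bound with the largest dual value
(shadow price) in the growth-maximization LP — one enzyme per iteration,
ties broken lexicographically so the audit trail is deterministic —
until `μ(1−f)` is reachable. The growth LP is capped at μ so the
corrected usages refer to the measured growth state. Released enzymes
enter `E_ref` at their usage in the final optimum (never below the
measurement, so the report invariant `relaxed ≥ original` holds);
untouched enzymes keep their measured values. Released bounds become
pool-limited rather than unbounded.

The baseline for an alternative condition first flexibilizes the
alternative measurements the same way, then solves the norm-minimal
projection (1-norm LP or 2-norm QP) and reports enzymes above a usage
floor of 1e-12 mmol/gDW — the working definition of "present in an
allocation" throughout the package.

Condition application relaxes measured uptake bounds multiplicatively
(+1% of the current magnitude per round, all bounds together) until the
growth target is reachable, and never tightens a bound.

## Evaluation

Predictions and baselines are compared on the intersection of supports
above the usage floor (log10 needs positive values; a configurable
pseudo-count mode exists for sensitivity analysis). Metrics: Pearson
correlation of the log10 vectors, and RMdSE =
sqrt(median of squared log10 gaps), with the even-count median taken as
the midpoint mean. Method comparisons use the two-sided Wilcoxon
rank-sum (Mann–Whitney) test — exact for groups under 10, normal
approximation with continuity correction otherwise — Bonferroni-scaled
by the number of method pairs and capped at 1. The λ sweep solves LP2 or
QP2 over a grid (default 0 to 1, step 0.1), scores each point against
the baseline, flags infeasible points, and breaks ties toward the
smallest λ. Reports carry both median (headline) and mean summaries.

## Synthetic study design

The generator emulates a microbe at desk scale: substrate uptake → a
trunk pathway of `n_linear` steps, each carried by **two
capacity-limited isozymes** → `n_branches` parallel routes of differing
**biomass yield** and finite capacity → biomass. Every internal reaction
has a dedicated enzyme with a log-uniform kcat (default 1–10 s⁻¹, the
bulk of measured turnover numbers). Route capacities (0.3–0.7 of demand
each) force demand to spread over several routes; sampled capacities are
scaled up when they cannot carry the reference growth rate, since a
reference condition supports its observed growth by definition.

These structural features are not decoration. In a bare chain/branch
toy, fluxes are fully determined by the growth rate, every solver
returns the same allocation, and the benchmark cannot distinguish
methods at all. Yield differences make route choice propagate upstream;
finite capacities give the flux system genuine freedom; isozyme pairs
let a measured bound stay binding in the baseline (its partner absorbs
the spill) instead of limiting growth and being flexibilized away.

The cell-side ground truth uses **effective** turnover numbers
`k_eff = k_nominal · 10^η`, `η ~ N(bias, spread)` per enzyme — the
in vivo/in vitro kcat gap. Defaults tie both to the noise knob:
spread = 2.5·σ and bias = +1.75·σ, so σ = 0.2 gives a 0.5-log10 scatter
with a systematic underestimation of in vivo rates by the nominal model,
the regime reported for apparent catalytic rates and the reason measured
abundances over-constrain pcGEMs in practice. At σ = 0 the effective and
nominal models coincide exactly. The planted reference allocation is the
enzyme-minimal allocation of the effective model at μ; the pool offered
to the solvers is calibrated on the *nominal* model's minimal demand
(×1.5 headroom), mirroring how pcGEM pools are fitted to observed
growth.

Alternative conditions perturb the model — `block_branch` (closes the
route carrying reference flux), `scale_uptake` (×0.6), `shift_kcat`
(degrades the active route's rates ×0.2, nominal and effective alike) —
and multi-seed benchmarks rotate through the three. The alternative
ground truth is either the cell's minimal-adjustment re-solve from the
noise-free reference under effective kinetics (**aligned** mode, the
hypothesis the predictors encode) or an independent enzyme-minimal
re-optimization (**adversarial** mode, the failure probe). Measurement
noise is lognormal per enzyme (normal in log10, default σ = 0.2, a
typical proteomics fold-change scatter), independent between the two
conditions.

What passing tests show, and what they do not: the synthetic study
demonstrates correct optimization, exact recovery in the noise-free
limit, and the qualitative superiority of minimal adjustment over
parsimony *under the aligned hypothesis with a realistic model-cell
kinetic gap*. Real proteomes have regulatory sectors, condition-dependent
saturation, and thousands of enzymes; toy results quantify none of that.

## Problem sizes and tolerances

Default toy models have ~12–16 reactions and ~10–14 enzymes; benchmarks
use 20 seeded condition pairs and finish in seconds. Oracle cross-checks
(GLPK for LPs, interior-point trust-constr for QPs, brute-force route
enumeration) run on models of ≤10 reactions at 1e-5 relative objective
tolerance. Feasibility contracts are verified at 1e-6 relative residual.
The usage floor (1e-12 mmol/gDW), the allocation-sum slack (1e-6
relative), and the λ grid step (0.1) are package-wide defaults.

## Known limitations

* Isozymes must be modelled as parallel reactions (GECKO convention);
  a shared-capacity pooling of alternative enzymes on one reaction is
  not supported.
* The baseline inherits the nominal model's kcat errors; it is a
  comparison construct, not a ground truth.
* `E_s,tot` must be supplied (or derivable from the condition); the
  package does not fit pool totals or saturation factors.
* Mass-weighted pools are supported only through molecular weights at
  import; all internal pool arithmetic is molar.
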