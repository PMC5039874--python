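# Methods

## Model structure and event ordering

The model is a deterministic Markov cohort recursion over five states:
four angina-severity states (minimal, mild, moderate, severe — ordered
by episode frequency) and absorbing death. Cycle length is 3 months
(0.25 years); the base case runs 4 cycles (1-year horizon) with no
discounting, which is exact for a horizon of at most one year. A
discounting hook (annual rate, per-cycle factors applied to rewards at
cycle start) exists for longer horizons.

Within a cycle, events are ordered as follows, and this ordering is the
model's fixed convention:

1. occupancy is measured at cycle start; all rewards for the cycle
   accrue on that distribution for the full cycle length (no half-cycle
   correction);
2. at cycle end each living patient dies with the cycle probability of
   the state occupied *during* the cycle;
3. survivors of cycle 1 transition between severity states according to
   the strategy's matrix; from cycle 2 onwards survivors remain in
   place, reflecting the absence of longer-term comparative efficacy
   data (the 3-month treatment effect is carried forward).

Mortality is state-dependent but treatment-independent. Annual
probabilities convert to cycle probabilities under a constant hazard:
`p_cycle = 1 − exp(ln(1 − p_annual)/4) = 1 − (1 − p_annual)^¼`, which
inverts exactly as `1 − (1 − p_cycle)⁴ = p_annual`.

## Parameter provenance and the packaged base case

The packaged base case ships the trial-derived 3-month transition
matrices, annual mortality by severity (4.6 / 4.8 / 8.1 / 10.9 %),
EQ-5D utilities (0.81 / 0.75 / 0.60 / 0.39), the symptomatic baseline
mix, annual per-state medical costs in five categories, and net monthly
drug costs of €29.18 (TMZ+SoC) and €23.40 (SoC), all in €2016.

The published transition percentages are rounded displays of exact
multinomial fractions over the per-state trial denominators, which are
recoverable from the printed values (for the add-on arm: 262, 184, 103
and 105 patients per origin state; for the comparator arm: 181, 191, 89
and 128). The fixture stores the exact fractions — e.g. the add-on
mild row is (97, 76, 10, 1)/184 — and the baseline distribution is the
symptomatic add-on-arm census (184, 103, 105)/392, which prints as
47 / 26 / 27 %. With these inputs the deterministic pipeline reproduces
the published per-arm table to within a few cents per category (the
residual traces to rounding of the printed monthly drug prices); with
the rounded two-decimal inputs instead, totals drift by about €2 and
the ICER by about 7 %. The row denominators are recorded in the fixture
metadata.

Configuration files express probabilities as fractions; any probability
above 1 is rejected outright to catch percentage/fraction unit
mistakes. Transition rows whose printed percentages sum to within 0.5 %
of 1 are proportionally renormalized; larger deviations are errors.

## Economic accounting

Per cycle, each medical category accrues `annual_cost/4` per unit of
state occupancy (death accrues nothing) and drug acquisition accrues
`monthly_cost × 3` on the proportion alive at cycle start — equivalent
to `monthly × 12 × life-years` over the horizon. The ICER is always
computed from unrounded totals. Comparisons are classified as equal,
intervention-dominant (ΔC < 0 < ΔE), comparator-dominant
(ΔE < 0 < ΔC) or tradeoff; the ICER is reported only for tradeoffs
with ΔE ≠ 0, so no division-by-zero path exists. Reporting precision
follows the field's convention: euros to 2 decimals, QALYs/LYs to 4.

## One-way sensitivity analysis

Default bounds are ±10 % for clinical inputs (transition cells,
utilities, annual mortality) and ±20 % for costs, applied
multiplicatively. Two row-rebalancing conventions are implemented for
transition-cell perturbation:

* **proportional** (the generic `perturb_parameter` default): the other
  three cells of the row are scaled by `(1 − new)/(1 − old)`;
* **stay-cell balancing** (used by the tornado): the change is absorbed
  entirely by the same-state cell, treating the stay probability as the
  derived remainder of the row. Under this convention the stay cells
  are not independent parameters and are excluded from the default
  handle set.

Drug acquisition prices are regulated quantities rather than sampled
estimates; they are excluded from the default tornado and explored
through dedicated scenarios instead (volume rebates of 2 % and 12 %
applied to both arms' net monthly costs; arbitrary price factors remain
available via `drug_cost:` handles). Bars are ranked by the width of
the signed ΔC/ΔE range across the two endpoints — well defined as long
as ΔE keeps its sign, including endpoints where the add-on becomes
dominant — falling back to the incremental-NMB range at the configured
WTP if ΔE changes sign or vanishes, so the ordering is always defined.
Utilities saturate at 1 under upward perturbation, as do transition
probabilities in the tornado's clamped mode.

## Probabilistic sensitivity analysis

Families follow the standard assignment for decision models: gamma for
costs (shape `1/cv²`, scale `mean·cv²`, preserving the mean), beta for
utilities and annual mortality (method of moments from the mean and an
effective sample size), Dirichlet for each transition row
(`α = row × ess`). Drug acquisition costs are held fixed. Structural
zeros (transitions never observed) remain zero; zero-valued costs stay
point masses.

The published analysis names these families but no variances, so the
defaults are this package's choice, exposed in `UncertaintySpec`:
`cost_cv = 0.102` (a ±20 % band as an approximate 95 % interval) and
`ess = 100` for every beta/Dirichlet family — deliberately round
values of the magnitude typical for expert-informed cost data and
trial-arm denominators. Under these defaults the probability of the
add-on being cost-effective at €34,000/QALY is about 0.86 over 5000
iterations; the exact value depends on the chosen variances, so it is
reported, not asserted. A degenerate spec (cv 0, infinite ess) turns
every draw into the base case and reproduces the deterministic results
bit-for-bit, which the tests assert.

One named generator (`numpy.random.default_rng(seed)`) drives a run;
the draw order is fixed (costs category-major, then utilities,
mortality, then transition rows per arm in origin order), so identical
seeds give identical results. Per-draw ICERs are never averaged;
threshold decisions use net monetary benefit.

## Synthetic data and the microsimulation oracle

`generate_random_parameters` draws structurally valid parameter sets:
Dirichlet(2,2,2,2) transition rows, utilities in (0.2, 0.95) decreasing
with severity, annual mortality in (0.005, 0.3) increasing with
severity, per-category costs increasing with severity (cumulative gamma
increments), baseline supported on the three symptomatic states. These
emulate the *shape* of real angina cost-utility inputs, not their
magnitudes or correlations; passing oracle tests demonstrates the
engine's arithmetic is right, not that any particular clinical dataset
is well modelled.

`microsimulate` is an independent individual-level implementation of
the same event ordering: it samples each patient's trajectory from the
input probabilities directly and never reuses the cohort recursion. By
default it uses balanced (stratified, randomized-remainder) allocation
at every stochastic branching — initial state, death, cycle-1
destination. Marginal per-patient probabilities are exactly those of
i.i.d. sampling, but empirical frequencies deviate from their
expectations by O(1/n) instead of O(1/√n), so the binomial/CLT standard
errors it reports are conservative upper bounds and the 3-SE
oracle-agreement checks in the test suite are sharp rather than flaky.
Plain i.i.d. sampling remains available (`balanced=False`). The oracle
test compares 20 random parameter sets at n = 50,000 patients each
(about 10 s), including exact equality for structurally deterministic
occupancy entries.

## Numerical conventions

Row-stochasticity is enforced to 1e-9 after construction; category
totals add to the overall total within 1e-6; trace rows conserve mass
to 1e-9 and dead occupancy is non-decreasing. Parameter containers are
immutable (frozen dataclasses over read-only arrays) so perturbation
and sampling can never corrupt a base case; equality is exact, which
makes serialization round-trips (`load(serialize(p)) == p`) testable
without tolerances.

## Known limitations

* No tunnel states, age-dependent background mortality, or horizons
  beyond what `n_cycles` expresses; the freeze-after-cycle-1 assumption
  is inherited from the 3-month efficacy window.
* Costs are state-membership averages; no patient-level cost
  heterogeneity beyond state, no indirect or out-of-pocket costs
  (third-party-payer perspective).
* PSA draws are independent across parameter families (the only
  correlation structure is within Dirichlet rows).
* No EVPI/EVPPI computation.
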