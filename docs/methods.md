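# Methods

## Model and estimators

Patients j = 1, …, N enter sequentially; patient j on arm i has response
y_j ~ N(μ_i, σ_i²) (a common σ unless stated). The trial has up to three
periods defined by the active-arm sets I₁ = {0, 1}, I₂ = {0, 1, 2},
I₃ = {0, 2}, with period fractions r_s and allocation probabilities p_{i,s}
summing to one within each period. Treatment effects are θ_i = μ_i − μ₀,
tested one-sided (H_i: θ_i ≤ 0) at α = 0.025 with two-sided 95% intervals.

The arm-i effect is estimated by the period-stratified estimator: the
treatment–control mean difference per period, combined across the arm's two
periods with inverse-variance weights w_{i,s} ∝ 1/σ_{i,s}², where
σ_{i,s}² = σ_i²/n_{i,s} + σ₀²/n_{0,s}. These weights minimize the combined
variance, and the estimator equals the treatment coefficient of an OLS
regression of y on arm indicators plus a period factor, fitted on the
arm's recruiting periods (periods 1–2 for arm 1, 2–3 for arm 2). The
package verifies this equivalence to 1e-10 against both the direct weighted
combination and the inverse information matrix.

Why stratify: if allocation ratios change between periods, a pooled mean
difference is biased by any drift in the response level over time. With a
period factor in the model, any trend that is additive and equal across
arms is absorbed, leaving the effect estimates unbiased and the test level
intact; the test suite demonstrates both the bias of the pooled contrast
and the calibration of the adjusted analysis under stepwise and linear
trends.

Non-concurrent controls: for arm 2, the same regression fitted on all three
periods additionally uses the period-1 controls (recruited before arm 2
entered). In a two-period trial this estimator has the explicit form
θ̃₂ = θ̂₂,₂ + ρ(θ̂₁,₁ − θ̂₁,₂) with
ρ = n₀,₂⁻¹/(n₀,₁⁻¹ + n₀,₂⁻¹ + n₁,₁⁻¹ + n₁,₂⁻¹): the twice-measured arm-1
effect calibrates the period effect. Its variance is, in inverse-precision
form (q_{i,s} = p_{i,s}(1 − p_{i,s})),

    N/σ² · Var(θ̃₂)⁻¹ = r₃q₂,₃ + r₂q₂,₂ − r₂²p₁,₂²p₂,₂² / (r₁q₁,₁ + r₂q₁,₂),

which never exceeds the concurrent-only variance and is strictly smaller
whenever r₁ > 0 and p₁,₂ > 0. The formula is validated against the inverse
information matrix of the full regression on expected counts (1e-14 in
spot checks, 1e-10 across 1,000 random designs in the suite). Arm 1 is
evaluated when its recruitment ends, so it always uses the concurrent-only
analysis. No unequal-variance version of the borrowing formula is provided;
`var_ncc` refuses unequal σ (known limitation).

## Optimal allocation

Objective: minimize max(Var(θ̂₁), Var(θ̂₂)) at fixed N; among minmax-ties,
the solution with the smaller minimum variance is returned (this pins equal
allocation in the single-arm periods where the maximum is insensitive to
them). Sample sizes are treated as positive reals throughout the
optimization; integer rounding only happens in the simulator.

- **Case 1** (free entry/exit): closed form — one period, control share
  1/(1 + √2), identical with or without non-concurrent controls.
- **Case 3, concurrent controls** (r₁, r₂ fixed): the scenarios r₁ ≥ ½ and
  r₁ + r₂ < ½ degenerate to one arm getting nothing in period 2 (ties
  classified to the boundary scenario). Otherwise the optimum is interior,
  the two variances are equal, and the Lagrange conditions give the
  stationarity relation p₀,₂² = p₁,₂² + p₂,₂² (re-derived here
  analytically; the symmetric anchor 1/(1+√2) falls out at r₁ = r₃). The
  solver runs a bracketed Brent root-find (xtol 1e-15) for the
  equal-variance condition along that curve; the bracket (0, ½) provably
  contains exactly one sign change in the interior regime.
- **Case 2, concurrent controls**: r₁ ≥ ½ gives two separate consecutive
  trials (r₂ = 0); otherwise r₂ = 1 − r₁ and the Case-3 interior solver is
  applied with r₃ = 0.
- **Non-concurrent controls, Cases 2–3**: no closed stationarity relation
  is available, so interior solutions minimize Var(θ̂₁) subject to equal
  variances with SLSQP from five deterministic starts (ftol 1e-14),
  followed by a bracketed root-find on the constraint at the winning point
  so the reported variance gap is at rounding level. Non-convergence from
  every start raises with the full start trace. The optimum always spends
  less on control than the concurrent-only solution at the same fractions.
- **Unequal variances** (concurrent only): single-arm periods get the
  Neyman split p_{i,s} : p_{0,s} = σ_i : σ₀; period 2 is solved by an
  epigraph SLSQP multi-start (maximize the smaller precision), with a
  secondary pass maximizing total precision among near-minmax points. With
  strongly unequal σ the optimum can be a genuine boundary point where the
  variances cannot be equalized (e.g. σ₂/σ₀ = 2 at equal thirds forces
  p₁,₂ = 0); the equal-variance property is therefore asserted only for
  interior solutions. Equal σ delegates to the closed-form Case-3 path.
- **Sum of variances**: the Lagrange conditions of Var₁ + Var₂ lead to the
  *same* stationarity curve as the minmax problem, so the solver is a
  bounded scalar minimization along the curve plus the two boundary
  candidates. At r₁ = r₃ the two criteria coincide at the √k rule. Away
  from symmetry the sum criterion shifts patients between the experimental
  arms (toward the arm with the smaller own-period share) relative to the
  minmax optimum; dense grid searches of both raw objectives show its
  control share is slightly *smaller* than the minmax one at asymmetric
  fractions — the package documents and tests this behaviour as found.

Numerical cross-checks: interior optima are compared against brute-force
searches of the raw objective. The minmax surface is kinked and nearly flat
along its equal-variance ridge (variations below 1e-5 over coordinate
ranges of several 1e-3), so a plain 0.002-step grid argmin can drift by a
few grid steps; the test oracle therefore polishes the coarse grid with a
profile search (exact inner scalar minimization) before comparing at 1e-3
per coordinate.

## Simulator

The generator emulates the package's case study: a phase II
placebo-controlled hypercholesterolemia platform trial with N = 92,
control responses Normal(4.94, 1) and treatment responses Normal(5.66, 1)
under the alternative — an effect of 0.72 SD chosen so that the √k
multi-arm design has 80% power at one-sided α = 0.025. These are the
generator defaults; the null sets all means to 4.94.

Integer sample sizes use two-level largest-remainder rounding: periods
first, then arms within periods. Exact ties are broken in favor of the
outer periods (so N = 92 in equal thirds gives 31/30/31 and symmetric
designs stay symmetric) and, within a period, in favor of control, then
arm 1. The three-period case-study rows instead use the published per-arm
count tables verbatim; their totals (94 and 93) are internally inconsistent
with N = 92, and they are used as printed.

Randomization is permuted-block within periods: realized group sizes equal
the nominal counts exactly, matching the sample-size tables the power
numbers refer to. Time trends are additive and equal across arms, either
linear in patient index (magnitude = total drift over the trial) or
stepwise per period (magnitude = per-period increment); suite scenarios use
magnitudes 0, 0.5 and 1 response SDs. Unequal-across-arms trends are out of
scope (the unbiasedness guarantee does not cover them).

The operating-characteristics engine vectorizes across replicates: one
response matrix per scenario, a single set of linear-algebra operations for
all model fits, rejection at the t (or z) critical value. Its per-replicate
decisions are bit-identical to running the patient-level inference path
trial by trial (enforced by a test). The default analysis is the t-test
with variance estimated from the residuals of each arm's model (df = n − p
of that model); a known-σ z-mode exists for exactness checks against the
closed-form variances. Degrees of freedom differ per arm because each arm's
model uses only its own periods.

Monte-Carlo sizes: the full case-study table runs 100,000 replicates per
scenario (MC standard error ≈ 0.0013 on a power of 0.8) and takes a few
seconds; the test suite uses 10,000 replicates (MC SE ≈ 0.004) and asserts
agreement with the published powers within ±0.02, which leaves room for the
~0.005 systematic slack from count rounding and test-mode conventions.

Confidence-interval widths are computed per arm from each fitted model.
The published case-study table lists identical widths for both arms in the
two-period rows, which per-arm model-based widths cannot reproduce (the
two arms' standard errors genuinely differ there); the package reports the
per-arm widths and leaves the discrepancy documented rather than matched.
CI widths are not part of the acceptance comparison.

## Degenerate inputs and conventions

- g(a, 0) = g(0, b) = 0: a period where one group is empty contributes no
  information; an arm never dosed alongside control gets an *infinite*
  variance flag, not an exception. Requesting a single period effect for an
  empty group raises `InestimableEffectError` (distinct from an invalid
  design).
- Inestimable period effects in the regression (no data in a period) are
  dropped and recorded in the estimate's metadata.
- Dummy coding: control is the reference arm, the earliest period in the
  fitted subset the reference period.
- All variances scale as 1/N; solvers work at N = 1 and report objectives
  in units σ²/N.

## Known limitations

- Two experimental arms, three periods, normal endpoints, no interim
  analyses, no multiplicity adjustment across the two hypotheses.
- The synthetic generator draws independent normal responses with exact
  per-cell counts; real trials have staggered individual entry within
  periods, covariates and non-normal outcomes, so passing tests show
  correctness of the design calculus, not robustness to those features.
- The non-concurrent-controls variance theory assumes a common σ across
  arms.
- Entry/exit times are treated as deterministic design parameters.
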