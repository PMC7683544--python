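# Methods

This note documents the models, the numerical choices, and the
synthetic-data design behind `rumenadapt`, and what the test suite
does and does not establish.

## Scales and conversions

Rumen acid status is handled on the hydrogen-ion concentration scale,
[H⁺] = 10^(−pH) mol/L, throughout the statistics; pH is a logarithm
and means, linear models and Euclidean distances computed on it weight
acid events inconsistently with the chemistry.  Conversion is exact
and bijective on positive reals; measurement tables carry both columns
and reject rows where supplied pH and [H⁺] disagree beyond 1e−6
relative (data integrity over silent preference).  Every analysis can
be rerun on raw pH via `scale="ph"`, and `compare_scales` tabulates
the two side by side.

## Sampling schedule

The reference design has nine sampling days: d1, d2 = d1+3 on the
standard diet; d3..d6 on four consecutive days right after the diet
change; then d7 = d6+4, d8 = d7+6, d9 = d8+7.  Week labels are
W1 = {d1, d2}, W2 = {d3..d6}, W3 = {d7}, W4 = {d8}, W5 = {d9}.  The
calendar gap between d2 and d3 is not fixed by the design; it defaults
to 4 days and is configurable — it only enters the analysis through
the weight of the d2→d3 trajectory step.  The short-term covariate
`days_since_change` is 1..4 on d3..d6 and 0 elsewhere, mirroring the
indicator that restricts the day slope to the first post-change week.

## Step 1: quadratic summary of post-prandial kinetics

Each animal-day curve (five time points: 0, 1, 2, 4, 6 h) is fitted
with [H⁺](t) = a·t² + b·t + c by ordinary least squares.  The model is
linear in its coefficients, so OLS finds the same optimum a nonlinear
optimiser on any re-parametrised form would; the re-parametrised
values are always reported.  Animal-days with fewer than 4 time points
(configurable, never below 3) are excluded with a logged warning.

Synthetic variables:

* v₀ = fitted value at t = 0 (pre-feeding baseline);
* t_peak = argmax of the fitted curve over the **closed** window
  [0, 6] — the vertex when a < 0 and it lies inside, otherwise the
  maximising endpoint.  Defining the amplitude A = value(t_peak) − v₀
  against the window maximum guarantees A ≥ 0 for any fit, including
  non-concave ones;
* v_last = fitted value at t = 6;
* R = (max − v₀)/(max − v_last) × 100.  This definition returns 100
  at exact return to baseline, below 100 when the curve overshoots the
  baseline, above 100 for incomplete recovery, and diverges as v_last
  approaches the maximum; R is reported missing (NaN, with a warning)
  when A = 0 or the denominator vanishes.  Because the divergence can
  be unwelcome, a `recovery_definition="complement"` switch computes
  (max − v_last)/(max − v₀) × 100 — the recovered fraction of the
  excursion — instead.  The ratio definition ("standard") is the default.

Threshold descriptors, for an acidosis threshold θ given in pH units
(default 5.5; literature range 5.5–6.0): dur = Lebesgue measure of
{t ∈ [0, 6] : fitted [H⁺](t) > 10^(−θ)}, computed analytically from
the quadratic's roots (strict exceedance), and amp_ac = window max −
10^(−θ), negative when the curve never reaches the threshold.  Both
are non-increasing in the threshold concentration.  v₀, A and R are
θ-free by construction.

In pH mode the excursion points downward: A = v₀ − window minimum,
dur = time the fitted pH sits below θ, amp_ac = θ − minimum, and R
mirrors to (min − v₀)/(min − v_last) × 100 so both conventions stay
positive.

### Inverse re-parametrisation

For a concave quadratic with an interior peak on a window of width W
(u = t − t₀):

    c = v₀,  A = −b²/(4a),  v_last − v₀ = aW² + bW,

and the R definition above yields b² W² − 4A b W + 4A²(1 − 100/R) = 0,
whose positive root with an interior vertex is

    b = 2A(1 + 10/√R)/W,  a = −b²/(4A).

Every triple with v₀ > 0, A > 0, R > 0 is feasible (the vertex
u* = W/(1 + 10/√R) always lies strictly inside the window).  The map
is validated by round-trip identity with the forward re-parametrisation
to 1e−9 relative over randomised triples.

## Step 2: longitudinal mixed model

Descriptors are power transformed as v^λ (log for λ = 0) with λ
maximising the Box-Cox profile log-likelihood over the grid [−2, 2] in
steps of 0.01.  The plain power is used rather than the
shifted-and-scaled Box-Cox form; at fixed λ they differ by a monotone
affine map, which changes no mixed-model test.  A Shapiro–Wilk check
of the raw descriptor is reported first; it gates a warning, never an
automatic decision.

The model is a random-intercept LMM: fixed week means α₁..α₅, a fixed
day slope β active only in the first post-change week, a per-animal
intercept G_i ~ N(0, σ_A²), i.i.d. residuals.  Fitting uses
statsmodels `MixedLM`.  Two numerical choices matter:

* the response is standardised to unit variance before fitting and
  all coefficients and variance components scaled back afterwards —
  power-transformed [H⁺] descriptors live at ~1e−2 magnitudes where
  some optimisers stall; LRT statistics and ρ are invariant to this
  affine rescale (a property the tests assert);
* ML fits feed the likelihood-ratio tests (REML likelihoods are not
  comparable across fixed-effect structures); REML fits supply the
  reported coefficients, variance components, ρ and BLUPs.

LRTs compare the full ML fit against (a) a single common intercept
replacing the week means — df = number of weeks − 1, i.e. 4 in the
reference design — and (b) the model without β — df = 1;
χ² = 2Δloglik floored at zero.  Post-hoc week contrasts use the REML
fixed-effect covariance with a normal approximation (denominator
degrees of freedom are ill-defined in small mixed models; the output
is flagged accordingly), Benjamini–Hochberg adjustment over the 10
pairs, and an insert-and-absorb compact letter display.

ρ = σ_A²/(σ² + σ_A²) ∈ [0, 1] by construction; σ_A² may legitimately
hit the boundary at 0 in small cohorts.

`power_simulation` draws datasets from the model at a supplied truth
over an n-animal × 9-day design, reruns the chosen LRT, and returns
the rejection fraction with its binomial standard error.  Published
power figures for designs like this depend on the parameter values
fitted to the original data, so the package asserts only the
qualitative properties: level ≈ α at zero effect, power increasing in
cohort size and effect size.

## Step 3: phase-plane scoring

For each animal, steps between consecutive sampling days in the
(v₀, A) plane score s = +2 (both coordinates decrease), −2 (both
increase), +1 (v₀ up, A down — the animal contains its amplitude
despite a rising baseline) or −1 (v₀ down, A up).  Zero changes count
as decreases by default (non-deterioration is credited; configurable);
when both deltas are zero the weight is zero and the convention is
moot.  The weight ω = Euclidean distance / calendar-day gap uses the
schedule's `day_offset` differences, so irregular sampling does not
bias the index.  The daily index is d = s·ω and the global index
GI = Σ d over the steps d2→d3 .. d8→d9.  The d1→d2 step (both days
pre-change) is excluded by default — the only convention consistent
with the published worked example's arithmetic — and a flag restores
the all-steps sum.

GI is equivariant under joint positive rescaling of the coordinates,
so the ×10⁷ display rescale (reported alongside the raw values) never
changes ranks, and |GI| ≤ 2Σω.  An unweighted variant (ω ≡ 1) is
provided for sensitivity checks: heavily losing animals keep their
rank under it, mid-field ranks may shuffle.

The quadrant rule generalises to n coordinates (first baseline-like,
rest amplitude-like): +2 if all decrease, −2 if all increase, else ±1
by majority of signs.  A tied majority is decided by the
amplitude-like coordinates alone, which reproduces the 2-D quadrants
exactly (the 2-D mixed step is always a 1–1 tie, and its sign follows
A); if those also tie, the baseline coordinate decides.  Only the 2-D
case is exercised by the validation suite.

## Synthetic cohorts

The generator inverts the full chain: per animal it draws random
intercepts for transformed v₀ and A; per animal-day it computes the
transformed means from the week pattern (plus optional day slope),
adds residual noise, back-transforms by the inverse powers
(λ_v0 = 0.20, λ_A = 0.28), draws R from a normal truncated to
(5, 100], builds the quadratic by the inverse re-parametrisation,
evaluates it at the five sampling hours, and multiplies by lognormal
measurement noise (default CV 3% on [H⁺], i.e. additive on pH, the
scale on which electrodes err).

Default week means follow the qualitative reference pattern — baseline
v₀ high on the standard diet, dipping after the change, rising
markedly in the final week; amplitude A climbing monotonically across
the challenge.  Variance components target intraclass correlations of
0.56 (v₀) and 0.17 (A) *as measured by the pipeline*: measurement
noise propagated through the Step-1 curve fit adds ≈0.23e−6 of
residual variance on the transformed-v₀ scale, and the mean of the
estimated ρ sits slightly below the variance-component ratio in
8-animal cohorts, so the generating components (σ_A² = 2.46e−6,
σ² = 1.51e−6 for v₀; 0.68e−6 and 3.32e−6 for A) were set so the
realised means land on target (verified: 0.575 ± 0.018 and
0.168 ± 0.011 over 60 cohorts).  A feasibility floor requires the
generated curve to stay above 25% of v₀ across the window; this keeps
simulated pH inside the physiological 5.0–7.5 band (realised
5.57–7.43) at the cost of truncating the effective R distribution at
its low end (draws implying near-zero end-of-window concentration are
rejected and R redrawn, with a retry cap).

What the generator does **not** emulate: feed-intake and rumination
covariates, serial correlation of residuals within a week, animal-by-
week interactions, missing-data mechanisms beyond optional uniform
drop-out, and any dependence of R on the diet (R is drawn i.i.d.,
consistent with its null week/day effects in the reference analysis).
Passing tests therefore show that the pipeline recovers the truth of
*this* generative structure at realistic noise — not that real rumen
data satisfy the model's assumptions.

## Problem sizes and tolerances

Validation uses 1,000 random triples/trajectories for the algebraic
round trips (tolerances 1e−9 and 1e−12 relative, the precision the
closed-form identities support), 1,000 simulated datasets for the null
calibration of the LRTs (acceptance band 3–7% at the nominal 5%),
200 full cohorts for ρ recovery, and 500 simulations per point for the
power checks (a day-effect of 0.0004 transformed units/day, ≈0.33
residual SD, chosen to spread the power curve across n = 8, 20, 40).
The acceptance script uses slightly smaller Monte-Carlo sizes (400
null datasets, 60 cohorts, 300 power simulations) — sizes at which the
binomial/Monte-Carlo error is already well inside the bands of
interest.

## Known limitations

* The quadratic cannot represent double-peaked or plateaued
  post-prandial curves; lack-of-fit shows up in `rss`, not in a shape
  change.
* The standard R definition diverges near v_last → max; downstream
  analyses drop undefined R values rather than imputing.
* Week contrasts use a normal approximation; with 8 animals the
  letters should be read qualitatively.
* GI carries no uncertainty statement (a residual bootstrap would be
  the natural extension).
* With variance components at the boundary (σ_A² = 0) REML fits emit
  convergence warnings that are suppressed; the reported ρ = 0 is the
  correct boundary estimate.
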