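# rumenadapt

Quantifying how well individual ruminants adapt to a high-concentrate
diet, from post-prandial rumen pH time series.

High-producing ruminants are fed diets rich in rapidly fermentable
carbohydrates.  Fermentation acids push rumen pH down after each meal,
and animals that cannot buffer the load slip into sub-acute ruminal
acidosis (SARA), with depressed intake and fibre digestion.  Within a
herd, some animals tolerate the challenge and others do not — but
ranking them requires condensing data sampled on two nested time
scales (hours within a day, days and weeks across the challenge) into
a single per-animal number.  `rumenadapt` implements a three-step
procedure that does exactly that, for designs such as: 8 cannulated
dairy goats, rumen pH measured at 0, 1, 2, 4 and 6 h after the morning
feed, on 9 sampling days spread over 5 weeks around an abrupt switch
from a 20% to a 50% concentrate ration.

All statistics run on hydrogen-ion concentration, [H⁺] = 10^(−pH),
because pH is a logarithm and linear statistics on it distort the
underlying chemistry (a pH flag reruns everything on the raw scale for
comparison).

## The three steps

**Step 1 — synthetic variables.**  Each animal-day curve is fitted
with a quadratic [H⁺](t) = a·t² + b·t + c and re-parametrised into
biologically meaningful descriptors: the baseline v₀ = [H⁺](0), the
amplitude A = max [H⁺] − v₀ over the 6-h window, and the recovery
descriptor R = (max − v₀)/(max − v_last) × 100.  Threshold-dependent
descriptors (time above an acidosis threshold θ, default pH 5.5, and
peak exceedance) are also computed, along with a Spearman screen of all
candidate descriptors.

**Step 2 — longitudinal mixed model.**  Each descriptor is Box-Cox
power transformed, then fitted with

v_ijk = α_j + G_i + β·(days_k·1{j=2}) + ε_ijk,  G_i ~ N(0, σ_A²),  ε ~ N(0, σ²),

where α_j are fixed week means (W1 = standard diet, W2–W5 on the new
diet), β a short-term day slope active only in the first post-change
week, and G_i a per-animal random intercept.  Fixed effects are tested
by ML likelihood-ratio tests, week contrasts get Benjamini–Hochberg
adjustment with a compact letter display, and the intraclass
correlation ρ = σ_A²/(σ² + σ_A²) measures how much of the variance is
between animals.  A Monte-Carlo power calculator covers both tests.

**Step 3 — phase-plane scoring.**  Each animal's (v₀, A) pair traces a
trajectory across sampling days.  Every step scores s ∈ {−2, −1, 1, 2}
by the quadrant of its change (both down = +2, both up = −2, mixed =
±1), weighted by ω = Euclidean displacement / calendar-day gap.  The
global index GI = Σ s·ω over the post-baseline steps ranks the animals:
higher (less negative) GI = better adaptive capacity.

A synthetic-cohort generator inverts the whole chain (mixed model →
(v₀, A, R) → quadratic → noisy measurements) so every stage is testable
against known ground truth.

## Worked example

```python
import rumenadapt as ra

measurements, truth = ra.generate_cohort(ra.default_params(seed=1))
descriptors = ra.fit_all(ra.annotate_schedule(measurements))

lam = ra.boxcox_lambda(descriptors["v0"])
result = ra.fit_mixed(descriptors, "v0", lam)
for test in ra.lrt_fixed_effects(descriptors, "v0", lam):
    print(test.effect, round(test.chi2, 1), test.df, f"{test.p_value:.2g}")
print("rho =", round(ra.icc(result), 2))

indices = [
    ra.global_index(ra.daily_scores(t), t.animal_id)
    for t in ra.trajectories_from_table(descriptors)
]
print(ra.rank_animals(indices)[["rank", "animal_id", "gi_display"]].round(2))
```

prints

```
week 119.3 4 7.6e-25
days 1.9 1 0.16
rho = 0.48
 rank animal_id  gi_display
    1     goat3        4.69
    2     goat6       -0.90
    ...
    8     goat2       -8.81
```

The week effect is strongly significant (the diet change shifted the
baseline acid load across weeks) while the short-term day slope is not;
48% of the baseline's variance is between animals; and goat3's positive
global index (×10⁷ display scale) marks the best adaptive response in
this simulated cohort.

The `examples/` directory has one short script per capability: curve
fitting, cohort simulation, the longitudinal model, trajectory scoring,
and the [H⁺]-versus-pH comparison.  A thin CLI mirrors the pipeline:
`rumenadapt simulate|fit-curves|lmm|score|run-all|compare-scales`.

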