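"""Model the week- and day-level effects of the diet change on v0.

Step 1 condenses each animal-day into synthetic variables; Step 2 asks
whether the high-concentrate diet shifted them.  The baseline v0 is
power transformed (Box-Cox), then fitted with a random-intercept mixed
model: fixed week means, a day slope restricted to the first
post-change week, and a per-animal intercept.
"""

import rumenadapt as ra

measurements, _ = ra.generate_cohort(ra.default_params(seed=1))
descriptors = ra.fit_all(ra.annotate_schedule(measurements))

lam = ra.boxcox_lambda(descriptors["v0"])
print(f"Box-Cox exponent for v0: lambda = {lam:.2f}")

result = ra.fit_mixed(descriptors, "v0", lam)
print(f"week means (transformed scale): "
      + ", ".join(f"W{w}={a:.4f}" for w, a in sorted(result.alpha.items())))
print(f"day slope beta = {result.beta:.2e}")
print(f"between-animal variance = {result.sigma_A2:.3e}, "
      f"residual = {result.sigma2:.3e}")
print(f"intraclass correlation rho = {ra.icc(result):.2f} "
      "(fraction of variance between animals)")

for test in ra.lrt_fixed_effects(descriptors, "v0", lam):
    print(f"LRT {test.effect:5s}: chi2({test.df}) = {test.chi2:.1f}, "
          f"p = {test.p_value:.2g}")

post = ra.posthoc_weeks(result)
print("compact letter display (weeks sharing a letter do not differ):")
print("  " + ", ".join(f"W{w}:{l}" for w, l in sorted(post.letters.items())))
# a significant week effect with W5 carrying its own letter reproduces
# the long-term rise in acid load the challenge is designed to induce
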