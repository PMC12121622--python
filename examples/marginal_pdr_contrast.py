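"""Standardized polyp-detection-rate contrast from a zero-inflated fit.

G-computation: predict P(Y > 0) for every subject with the exposure set to
1, then to 0, and average.  The difference and odds ratio of the two
averages are marginal effect sizes on the PDR scale — comparable across
model families, unlike the conditional coefficients.  CIs are a seeded
percentile bootstrap (subjects resampled, model refit).
"""

from zicount import (REFERENCE_SCENARIOS, fit_zero_inflated, generate_dataset,
                     standardized_pdr_contrast)

data, _ = generate_dataset(REFERENCE_SCENARIOS[1], seed=13)
model = fit_zero_inflated(data, "poisson")
res = standardized_pdr_contrast(model, data, n_bootstrap=200, seed=42)

print(f"estimated PDR (observed covariates): {res.estimated_pdr:.3f}")
print(f"PDR if everyone exposed:   {res.pdr_group1:.3f}")
print(f"PDR if everyone unexposed: {res.pdr_group0:.3f}")
d_lo, d_hi = res.ci_difference
o_lo, o_hi = res.ci_or
print(f"marginal difference: {res.marginal_difference:+.3f} [{d_lo:+.3f}, {d_hi:+.3f}]")
print(f"marginal odds ratio: {res.marginal_or:.2f} [{o_lo:.2f}, {o_hi:.2f}]")
print("\nA difference near 0 with a clearly positive count-part RR is the "
      "signature pattern: the exposure finds more polyps per detected "
      "subject without changing who has any detected at all.")
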