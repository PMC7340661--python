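"""Fit the adjusted Bernoulli power law to a synthetic training cohort.

Generates a 21-patient cohort under the default study conditions, fits
the reduced-form power law by trust-region least squares and prints the
coefficients with 95% Wald confidence intervals.
"""

from tpgmodel import CohortConfig, confidence_intervals, fit_cohort, sample_cohort

cohort = sample_cohort(CohortConfig(seed=7))
print(f"training cohort: {len(cohort)} cases, {int(cohort.excluded.sum())} excluded")

fit = fit_cohort(cohort)
ci = confidence_intervals(fit, 0.95)

print(f"c     = {ci.c:7.3f}  95% CI [{ci.ci_c[0]:.3f}, {ci.ci_c[1]:.3f}]")
print(f"alpha = {ci.alpha:7.3f}  95% CI [{ci.ci_alpha[0]:.3f}, {ci.ci_alpha[1]:.3f}]")
print(f"beta  = {ci.beta:7.3f}  95% CI [{ci.ci_beta[0]:.3f}, {ci.ci_beta[1]:.3f}]")
print(f"R²    = {fit.r2:.3f}, SEE = {fit.see:.2f} mmHg over n = {fit.n}")
print()
print("With noise off the oracle coefficients (3.007, -0.373, -0.216) are")
print("recovered exactly; under the calibrated residual noise the fit")
print("should land within the intervals above in ~95% of cohorts.")
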