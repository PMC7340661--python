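"""End-to-end study replication: train cohort -> fit -> test cohort -> report.

Mirrors the full analysis workflow on synthetic data: fit the power law
on a training cohort, then score all three estimators on an independent
test cohort.
"""

import numpy as np

from tpgmodel import (
    CohortConfig,
    confidence_intervals,
    evaluate_estimators,
    fit_cohort,
    sample_cohort,
)

seed = 2026
train_seed, test_seed = [
    int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(2)
]

train = sample_cohort(CohortConfig(seed=train_seed))
fit = fit_cohort(train)
ci = confidence_intervals(fit)
print(f"fitted on {fit.n} training cases: c={ci.c:.3f}, alpha={ci.alpha:.3f}, "
      f"beta={ci.beta:.3f} (R²={fit.r2:.3f}, SEE={fit.see:.2f} mmHg)")

test = sample_cohort(CohortConfig.test(seed=test_seed))
reports = evaluate_estimators(test, ci, threshold=40.0)
print(f"test cohort: {len(test)} cases, mean true TPG "
      f"{test.tpg_true_mmhg.mean():.1f} mmHg")
for name, rep in reports.items():
    print(f"  {name:15s} bias {rep.mean_diff:6.2f} mmHg, SEE {rep.see:5.2f} mmHg, "
          f"FP {rep.n_fp}, FN {rep.n_fn}")
print()
print("The adjusted model's bias and scatter against ground truth should be")
print("several-fold smaller than the classical Bernoulli estimator's, with")
print("fewer false severe-stenosis calls at the 40 mmHg threshold.")
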