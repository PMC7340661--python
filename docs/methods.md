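# Methods

## Model

The package estimates the net transvalvular pressure gradient (TPG,
mmHg) of an aortic stenosis from two routinely measurable quantities:
the aortic valve area AVA (cm², projected leaflet-rim area) and the
volume flow rate Q (l/s). The adjusted Bernoulli model generalises the
clinical equation TPG = 4·v_max² in two ways: the constant coefficient
becomes a power law in (AVA, Q), and the peak velocity is replaced by
the area-averaged velocity ṽ = Q/AVA, which needs no extra measurement:

    TPG = c · AVA^α · Q^β · ṽ²,     ṽ [m/s] = 10 · Q / AVA.

Substituting ṽ gives the reduced form TPG = c′·AVA^(α−2)·Q^(β+2) with
c′ = 100·c; the factor 100 is the square of the unit factor 10 and is a
consequence of fixing AVA in cm², Q in l/s, ṽ in m/s. Both forms are
implemented and verified identical to 1e−10 relative. The reference
coefficients (c, α, β) = (3.007, −0.373, −0.216) describe a
mild-to-moderate stenosis population; the model is a quasi-steady,
population-calibrated correction, not a patient-specific flow solution.
Because α and β are small and negative, the effective coefficient
c·AVA^α·Q^β lies below the clinical 4 for most states — consistent with
the classical estimator's systematic overestimation of the recovered
(net) gradient — and rises for small orifice areas.

Supporting physics implemented alongside: the dimensional Bernoulli
coefficient ½ρ/133.32 = 3.9379 (ρ = 1050 kg/m³), the Gorlin valve-area
formula AVA = CO/(HR·SEP·√TPG_mean·44.3) in its classical units
(CO mL/min, HR bpm, SEP s/beat) with its exact inverse, the
Borda-Carnot sudden-expansion loss ξ·½ρ(v₁−v₂)² with ξ ∈ [0, 1], the
equivalent orifice diameter D = 2√(AVA/π), the orifice Reynolds number
ρ·ṽ·D/η with constant high-shear viscosity η = 0.0035 Pa·s (the full
shear-thinning rheology belongs to resolved CFD, out of scope here),
and the peak↔mean gradient conversion TPG_ps = a·TPG_mean with the
guideline range a ∈ [1.56, 1.68] enforced as a warning.

## Fitting

`fit_power_law` minimises Σ(c′·AVA^a′·Q^b′ − TPG)² over the reduced
parameters with scipy's trust-region-reflective least squares —
unweighted ("no robust function"), unbounded, tolerances
ftol = xtol = gtol = 1e−10, at most 500 residual evaluations.
Initialisation is ordinary least squares on the log-log linearisation
log TPG = log c′ + a′·log AVA + b′·log Q (rows with TPG ≤ 0 are dropped
from the initialisation only; if fewer than three remain the start
point is the clinical Bernoulli equivalent c′ = 400, a′ = −2, b′ = 2).
The solver's objective can only improve on the start point; this is
asserted in tests. A design in which every AVA and every Q is constant
leaves the exponents undetermined and raises an identifiability error;
hitting the iteration cap returns a result flagged `converged=False`
rather than raising.

Confidence intervals are Wald-type: covariance s²(JᵀJ)⁻¹ from the
Jacobian at the solution, s² = SSE/(n−3), t quantile at n−3 degrees of
freedom. They are computed in the reduced parameterisation and mapped
to (c, α, β) by the exact linear transformations c = c′/100, α = a′+2,
β = b′−2. Their calibration is validated by simulation — nominal 95%
intervals cover each true coefficient in 95 ± 3% of 1000 replicate
cohorts under additive homoscedastic Gaussian noise, the error
structure this covariance assumes. The coverage harness adds its own
unfloored noise to noiseless cohort designs; the generator's additive
mode floors gradients at zero to keep them physical, which would bias a
coverage study. Under the generator's default multiplicative noise
(heteroscedastic) the Wald intervals are approximate.

Two SEE conventions coexist deliberately: the fit reports the residual
standard error with n−3 degrees of freedom (three fitted parameters),
while the evaluation module uses the regression-based SEE with n−2
degrees of freedom (slope and intercept of the line truth ~ estimate),
the convention under which estimator comparisons are reported.

## Synthetic cohort generator

The generator emulates the statistical structure of a CT-derived CFD
stenosis study; it does not emulate anatomy, waveforms, or imaging.
Defaults (the study conditions):

| quantity | distribution | default |
|---|---|---|
| patients | — | 21 (training preset), 4 (test preset) |
| open-valve phases/patient | uniform integer | 1–4 (training), 3 (test) |
| AVA [cm²] | truncated normal | 1.87 ± 0.87 on [0.64, 4.37] |
| base flow Q [l/s] | truncated normal | 0.217 ± 0.109, positive |
| flow multipliers | fixed set | {1, 1.5, 2.5, 3} (training), {1, 1.5, 2.5} (test) |
| profile ratio ṽ/v_max | truncated normal | 0.85 ± 0.082 on [0.59, 0.96] |
| residual noise at mean TPG | log-normal (default) | 2.91 mmHg |
| exclusion thresholds | strict > | v_max 8 m/s, TPG 200 mmHg |

Truncated normals are sampled by rejection (exact; only mean ± SD and
range are known, the normal family is a modelling choice). AVA and the
profile ratio are properties of a phase's geometry and flow field, so
they are shared across the multiplier replicates of that phase — hence
ṽ and v_max scale exactly linearly with the multiplier and v_max ≥ ṽ
always holds. The test preset uses 4 patients × 3 phases × 3
multipliers = 36 cases.

The ground-truth oracle is the adjusted power law at the reference
coefficients (so noiseless generation followed by fitting is an exact
end-to-end identity), with multiplicative log-normal residual noise:
TPG = TPG_det·e^ε, ε ~ N(0, σ²), σ = 2.91/mean(TPG_det) so the additive
spread at the cohort-mean gradient matches 2.91 mmHg while the spread
grows with the gradient, as Bland-Altman plots of simulation-vs-model
residuals suggest. An additive Gaussian alternative (floored at zero)
is switchable. A Borda-Carnot-style oracle — expansion loss of the
transvalvular jet into a fixed 7 cm² ascending aorta — is provided to
exercise the fitter under model misspecification; it is deliberately
not a power law in (AVA, Q) alone.

Exclusion uses OR across the two thresholds with strict inequalities;
boundary values are retained. Flagged records are kept with their
reason, never deleted.

What passing tests on this generator do **not** show: robustness to
measurement error in AVA and Q (the same values feed oracle and
estimators), to bicuspid or severely stenosed valves outside the
sampled ranges, to waveform/pulsatility effects, or to real profile
ratios, which correlate with jet complexity rather than being
independent draws.

## Evaluation protocol

For each estimator (peak-velocity Bernoulli, average-velocity
Bernoulli, adjusted model) over the retained records: differences are
estimate − truth; Bland-Altman reports their mean, sample SD (n−1) and
mean ± 1.96·SD limits of agreement; Pearson r with r²; the SEE of the
OLS line truth ~ estimate (n−2 dof); false positives/negatives at the
40 mmHg threshold with strict "above"; Shapiro-Wilk on the differences
and a two-sided Wilcoxon signed-rank test (all-zero differences are
flagged degenerate with p = 1 rather than erroring).

A 50-seed train/test replication shows the study-shaped ordering: the
adjusted model's |bias| is below the average-velocity Bernoulli's,
which is below the peak-velocity Bernoulli's, for every seed. The
analogous per-seed SEE chain is **not** guaranteed at 36 test cases: a
test cohort contains only 12 independent profile ratios and SEE is
dominated by its few highest-gradient cases, so SEE(avg) vs SEE(max) is
a near-tie that flips in roughly a fifth of seeds (and adjusted vs avg
in a few percent), while the across-seed medians order correctly
(≈3.2 < 5.9 < 7.2 mmHg). The acceptance battery asserts the strict
per-seed chain for both metrics and therefore documents this
small-sample limitation by failing on it; the module tests assert the
per-seed bias chain and the median SEE ordering, which the generator
does guarantee.

## Numerical choices and problem sizes

Seeds: one integer per cohort; multi-cohort workflows spawn independent
child streams via `numpy.random.SeedSequence` (derived seeds kept below
2³¹). Default test-battery sizes — 1000 coverage replicates at ~135
records, a 201³ grid search on 20-record tables (solved exactly per
(a′, b′) pair via the quadratic structure in c′), 50-seed ordering
suites — run in well under a minute in total. Zero flow returns a zero
gradient (the ṽ² factor dominates the weak negative-exponent
singularity); zero-noise configurations are exactly deterministic;
cohort CSVs are byte-identical across runs with the same seed.

## Known limitations

The model is dimensional (coefficients valid only in the stated units)
and population-calibrated; it does not capture valve-shape effects,
severe stenosis (AVA < 1 cm² is at the edge of the sampled range), or
pressure-recovery geometry beyond what the training population encoded.
The synthetic generator's independence assumptions (profile ratio,
noise) make some real-data failure modes invisible, as noted above.
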