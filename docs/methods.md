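# Methods

## Response distribution

The response family is the Generalized Inverse Gaussian in its **mean
parameterization** (μ, σ, ν): with b = 1/σ² and c = K_{ν+1}(b)/K_ν(b),

    f(y) = (c/μ)^ν y^{ν−1} / (2 K_ν(b)) · exp{ −(b/2)(cy/μ + μ/(cy)) },  y > 0,

which maps onto the classical (λ, χ, ψ) form via λ = ν, √(χψ) = b,
√(χ/ψ) = μ/c, and has E[Y] = μ exactly.  Two consequences drive the
implementation:

* μ is a **pure scale parameter** — every quantile is proportional to μ,
  so a log-link regression on μ shifts the whole distribution
  multiplicatively, and per-subject quantile prediction only needs one
  unit-mean quantile per distinct (σ, ν) pair.
* the log-density is evaluated entirely in log space with exponentially
  scaled Bessel functions (`scipy.special.kve`), stable for responses to
  at least 10⁴ mm/h and for b from ~10⁻⁴ to ~10¹⁰.

The density, classical-form conversion, moments (closed form
η^k K_{λ+k}(ω)/K_λ(ω)) and quantile calibration are implemented here;
cdf/ppf/rvs delegate to `scipy.stats.geninvgauss` after conversion.  The
package's tests keep independent routes for all of these: adaptive
quadrature for normalization and moments, the inverse-Gaussian closed
form at ν = −1/2, and Kolmogorov–Smirnov agreement between the sampler
and the cdf — so the scipy backend is continuously cross-checked rather
than trusted.

**Quantile calibration.**  `gig_calibrate_quantiles` matches three
(probability, value) targets.  Because μ cancels from quantile ratios,
the two log-ratios are solved for (log σ, ν) by least squares from four
starting points, after which μ follows in closed form from the middle
target.  Residual tolerance is 10⁻⁶ relative; failure raises with the
achieved residuals rather than returning a bad fit.  The sex-specific
defaults of the cohort generator are the calibration products for the
published quartiles — female (7, 12, 21) → μ ≈ 16.63, σ ≈ 0.90,
ν ≈ −0.40; male (3, 6, 12) → μ ≈ 9.41, σ ≈ 1.17, ν ≈ 0.00 — frozen in
`simulate.py` so a default configuration needs no solver run.

## Covariate coding rules

All rules are pure functions (see `cohort.py`): alcohol 10 g per glass of
wine or bottle of beer and 20 g per spirit unit, with bands 0 / 1–140 /
141–279 / ≥280 g per week; smokers are ≥1 cigarette/day or quit within
the last year (quitting exactly 1.0 year ago counts as within — the
boundary is not otherwise determined); BMI classes <25 / 25–30 / >30
with 30.0 itself read as overweight (honouring both printed interval
ends); ATP-III metabolic syndrome as ≥3 of the five printed criteria
with their exact inequalities (waist strictly >, triglycerides and
glucose ≥, HDL strictly <); IPAQ short-form scoring with the official
MET coefficients (walking 3.3, moderate 4.0, vigorous 8.0), the
moderate/high criteria as published, activity-days combined additively
across intensities, and precedence high > moderate > low.  Missing
required fields are handled by complete-case exclusion with a count in
the output's `attrs` — no imputation.

## Synthetic cohort generator

The generator emulates the survey design: seven age strata (18–29 …
70–79, 80+) with equal n (default 500), uniform age within stratum, sex
Bernoulli(0.445 male).  Categories (smoking, alcohol, activity, BMI
class, metabolic syndrome) are sampled first from configured
prevalences, then the raw questionnaire/laboratory fields are
**back-filled** from ranges that the coding rules map back onto exactly
that category — the inverse of the analysis direction, chosen so the
fixture is rule-consistent by construction.  Real prevalences for the
source population are not machine-readable, so the defaults are
documented plausible adult-population marginals.

ESR is the generative model read forward: log μ = sex baseline + Σ
covariate effects + f(age), log σ = sex baseline + slope·(age − 50),
ν per sex from the calibrated baselines.  Default effect directions
follow the reported multivariable associations (positive: age, female
sex, BMI class, metabolic syndrome, current smoking; negative: light
alcohol, high activity, hemoglobin); magnitudes (±0.03…0.15 on log μ)
were chosen once as plausible modest effects.  The age effect is
anchored at age 50 (≈ the cohort median age), so the baselines calibrated
to the published quartiles describe a mid-cohort adult; its default is a
monotone quadratic with amplitude log 2 between ages 18 and 75, making
the over-65 groups' median ESR about twice the 18–35 group's.
`ground_truth` reports every coefficient in the fitter's
parameterization (female intercept, `sex=male` contrast, dummy effects,
evaluable f(age)).

What the generator does **not** emulate: the real joint covariate
distribution (only configured marginals plus the built-in age/sex
structure), measurement error in the assays, and any residual dependence
between lifestyle covariates.  Passing tests therefore demonstrate
correctness of the pipeline under the stated generative model, not
agreement with any real cohort's numbers.

## Fitting

The penalized log-likelihood is maximized **jointly** over μ-coefficients,
σ-coefficients and ν with L-BFGS-B.  Gradients chain the exact design
products onto per-observation derivatives of the log-likelihood in the
linear predictors, obtained by central differences (two vectorized
evaluations per predictor, h = 10⁻⁵) — the ν-derivative of the GIG
log-likelihood involves Bessel-function order derivatives with no stable
closed form, so a fully analytic gradient was not pursued.  Convergence
uses scipy's ftol 10⁻¹¹ / gtol 10⁻⁶ (successive penalized log-likelihood
changes well below 10⁻⁶); a failed line search triggers one restart from
the incumbent before raising, with the objective trace attached.
Linear predictors are soft-clipped (|log μ| ≤ 25, |log σ| ≤ 10) and any
non-finite likelihood returns a large finite objective so line searches
back off gracefully.  Numeric covariates are standardized internally;
coefficients are reported back on the raw scale.

**P-splines.**  Cubic B-splines with 20 equally spaced interior knots by
default (tests and the Monte-Carlo studies use 12 — at n ≈ 2000–3500 the
penalty, not the basis size, governs flexibility), 2nd-order difference
penalty, and a sum-to-zero constraint (null-space projection of the
column-sum constraint) for identifiability next to the intercept.  For
each smoothing value λ the spline block is rotated onto the penalty
eigenbasis and scaled by 1/√(1 + λs_j); in these coordinates the penalty
is diagonal and bounded by 1, so the optimization stays well conditioned
from λ = 10⁻² to 10⁶ (this rescaling cut worst-case iteration counts by
~30×).  λ is selected by BIC over a descending log-spaced grid (10⁶ →
10⁻², 9 points), warm-starting each fit from the previous one and
stopping after BIC has worsened twice — BIC along the grid is in
practice unimodal.  Ties in model selection break toward fewer effective
df.

**Effective degrees of freedom.**  At the converged fit, per-predictor
working weights w_i = −∂²ℓ_i/∂η_i² (central differences, floored at
10⁻⁸) give the influence matrix; a spline term's edf is the trace of its
block of (XᵀWX + λP)⁻¹XᵀWX, unpenalized terms count 1 per coefficient,
and ν adds 1.  BIC is exactly −2ℓ + df·log n with the unpenalized ℓ.

**Degenerate inputs** are rejected with named errors: non-positive
responses, rank-deficient designs (collinear columns are identified via
the QR diagonal), unknown category levels, P-splines on non-numeric
covariates, covariates repeated within a predictor.

## Diagnostics

Quantile residuals are z_i = Φ⁻¹(F_GIG(y_i; μ̂_i, σ̂_i, ν̂)) with F
clipped to [1/(2n), 1 − 1/(2n)].  Worm plots detrend the normal Q-Q of
the ordered residuals and carry the pointwise 95% band ±1.96·√(p(1−p)) /
(√n·φ(Φ⁻¹(p))) at p_i = (i−½)/n.  The package deliberately fits only the
GIG family; the worm plot shows *whether* extra skewness/kurtosis
modelling would be needed, but acting on that is out of scope.

## Reference values

`reference_table` reads "average predicted value within each age-and-sex
group" literally: each member's predicted p-quantile is computed from
their own fitted (μ, σ, ν) and averaged within the (sex, age-bin) cell.
This is covariate-profile-free and reduces to the member's own quantiles
for singleton cells.  The alternative — evaluate at the cell's average
linear predictor (≈ bin midpoint with reference covariates) — is
available behind `at_midpoint=True`.  Default bins 18–35 / 35–50 /
50–65 / >65 (youngest and oldest categories as contrasted in the source;
interior boundaries chosen at round 15-year steps), configurable.
Percentiles are reported to 0.1 mm/h, percentages to 0.1%.  Exceedance
counting against the laboratory limits (20 mm/h males, 30 mm/h females)
uses strict inequality.  Mann–Whitney group comparisons are implemented
from the midrank rank-sum definition, with exact full-enumeration
p-values for n₁+n₂ ≤ 12 and the tie-corrected, continuity-corrected
normal approximation otherwise; tests cross-check both regimes against
an independent implementation.

## Problem sizes used in validation

The Monte-Carlo validation studies use cohorts of 7 × 215 ≈ 1500 (20
replicates for coefficient recovery, 12 per truth for BIC form
selection, well-specified generative configs with shared σ/ν across
sexes), n ≈ 5000 for residual calibration, and n = 5000 resampled
subjects for percentile-coverage calibration; the calibration medians
use 10⁵ draws.  These sizes give Monte-Carlo error comfortably inside
the asserted tolerances (e.g. binomial 3 SE bands for coverage) while
keeping the full suite quick to run.

## Known limitations

* ν is a single constant; covariate-dependent shape (and other GAMLSS
  families) are out of scope by design.
* One shared smoothing parameter when a spec contains several P-spline
  terms.
* The Demmler–Reinsch rescaling assumes the difference penalty is
  positive semidefinite (true for difference penalties).
* Standard errors / confidence bands for coefficients and percentile
  curves are not provided (none are needed by the pipeline's outputs).
* Prediction clamps covariates outside the observed spline range to the
  range boundary rather than extrapolating.
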