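# esrref — distributional regression reference values for the erythrocyte sedimentation rate

The erythrocyte sedimentation rate (ESR, mm/h) is a routine inflammation
marker that is strongly right-skewed, roughly twice as high in females as
in males, and rises steadily with age — so a single "normal range" is a
poor clinical yardstick.  This package implements the full statistical
pipeline for building **age-and-sex-specific ESR reference values** from a
population survey, for biostatisticians and laboratory scientists who
want covariate-adjusted centile cut points rather than one-size-fits-all
limits.

## The model

ESR is modelled with a **Generalized Inverse Gaussian (GIG)** response —
a three-parameter positive distribution (mean μ, scale σ, shape ν) whose
normalizing constant involves the modified Bessel function of the second
kind, well suited to strongly right-skewed biomarkers.  In the GAMLSS
(Generalized Additive Models for Location, Scale and Shape) style, both
distribution parameters are regressed on covariates through log links:

    log μ_i = β₀ + Σ_j f_j(x_ij)        log σ_i = γ₀ + Σ_j g_j(x_ij)

where each covariate enters as a constant (omitted), a linear term, or a
**penalized cubic B-spline** (P-spline, 2nd-order difference penalty).
All coefficients, the smoothing level and the constant shape ν are chosen
by penalized maximum likelihood with **BIC** (−2ℓ + df·log n, spline df =
trace of the smoother influence matrix) for model and smoothing
selection.  Model adequacy is checked with **normalized quantile
residuals** (Φ⁻¹ of the fitted cumulative probability; standard normal
iff the model is right) and **worm plots** (detrended Q-Q with 95%
pointwise bands).  Reference cut points are the average predicted 90th,
95th and 97.5th percentiles within each age-and-sex group.

Around the model sit the survey's deterministic coding rules — weekly
alcohol grams from standard drinking units (wine/beer ≈ 10 g, spirits
≈ 20 g), smoker/ex-smoker/never classification, IPAQ short-form
MET-minutes and low/moderate/high activity, BMI classes, and the ATP-III
metabolic-syndrome count — plus a synthetic cohort generator that
emulates the survey design (seven age strata × 500, 44.5% male) with a
known generative truth for validation.

## Worked example

```python
import numpy as np
import esrref as E

# a survey-design cohort with known generative parameters
cohort  = E.simulate_cohort(E.SimulationConfig(n_per_stratum=300, seed=7))
derived = E.derive_table(cohort)

# compare age-effect forms on log-mu by BIC
best, ranking = E.select_model(derived, [
    E.ModelSpec(mu_terms=(E.Term("age", "constant"), E.Term("sex", "linear")), name="constant"),
    E.ModelSpec(mu_terms=(E.Term("age", "linear"),   E.Term("sex", "linear")), name="linear"),
    E.ModelSpec(mu_terms=(E.Term("age", "pspline"),  E.Term("sex", "linear")), name="pspline"),
])
print(ranking.round(1))
print(E.reference_table(best, derived))
```

prints (seed 7):

```
      model  loglik  total_df      bic
0   pspline -7736.5       6.5  15522.7
1    linear -7755.1       5.0  15548.5
2  constant -7904.0       4.0  15838.7
      sex  age_low  age_high    n   p90    p95  p97.5
0  female     18.0      35.0  252  34.9   47.7   61.7
1  female     35.0      50.0  247  38.3   52.4   67.7
2  female     50.0      65.0  255  47.7   65.3   84.3
3  female     65.0     120.0  417  77.9  106.7  137.8
4    male     18.0      35.0  197  16.0   21.9   28.3
5    male     35.0      50.0  204  17.7   24.2   31.3
6    male     50.0      65.0  200  21.6   29.6   38.2
7    male     65.0     120.0  328  36.0   49.2   63.6
```

The smooth age effect wins on BIC (the generator's age effect is curved),
and the table gives the upper ESR cut points in mm/h per age-and-sex
group — e.g. 97.5% of 18–35-year-old males in this synthetic population
are predicted below ≈ 28 mm/h, versus ≈ 138 mm/h for women over 65.

The `analysis/` scripts run the same pipeline as a narrative sequence
(`01_simulate_cohort.py` … `05_reference_values.py`), writing summary
tables under `results/` and large intermediates under `scratch/`.

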