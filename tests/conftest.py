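import numpy as np
import pytest

from esrref import (
    AgeEffect,
    GIGParams,
    ModelSpec,
    SimulationConfig,
    Term,
    derive_table,
    fit,
    simulate_cohort,
)
from esrref.simulate import FEMALE_BASELINE

# printed sex-specific ESR quartiles (mm/h) used for calibration checks
FEMALE_QUARTILES = [(0.25, 7.0), (0.5, 12.0), (0.75, 21.0)]
MALE_QUARTILES = [(0.25, 3.0), (0.5, 6.0), (0.75, 12.0)]


def recovery_config(kind="linear", amplitude=0.5, seed=0, n_per_stratum=215,
                    smoker_effect=0.0):
    """A generative config the fitter's model class contains exactly:
    shared sigma/nu across sexes, no lifestyle or hemoglobin effects
    unless requested, and a chosen age-effect shape."""
    F = FEMALE_BASELINE
    effects = {k: 0.0 for k in SimulationConfig().mu_effects}
    effects["smoking_category=smoker"] = smoker_effect
    return SimulationConfig(
        n_per_stratum=n_per_stratum,
        seed=seed,
        baseline={"female": F, "male": GIGParams(F.mu / 2.0, F.sigma, F.nu)},
        mu_effects=effects,
        hemoglobin_coef=0.0,
        age_effect=AgeEffect(kind=kind, amplitude=amplitude),
        sigma_age_slope=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimulationConfig(n_per_stratum=60, seed=42))


@pytest.fixture(scope="session")
def small_derived(small_cohort):
    return derive_table(small_cohort)


@pytest.fixture(scope="session")
def linear_fit(small_derived):
    spec = ModelSpec(
        mu_terms=(Term("age", "linear"), Term("sex", "linear")),
        sigma_terms=(Term("sex", "linear"),),
    )
    return fit(small_derived, spec)
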