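"""Distributional regression fitter: recovery, penalties, BIC, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from esrref import (
    FittedModel,
    GIGParams,
    InvalidInputError,
    ModelSpec,
    Term,
    bic,
    derive_table,
    fit,
    gig_quantile,
    gig_rvs,
    ground_truth,
    quantile_residuals,
    select_model,
    simulate_cohort,
    worm_plot_data,
)
from tests.conftest import recovery_config


def _intercept_only_frame(params: GIGParams, n: int, seed: int) -> pd.DataFrame:
    y = gig_rvs(n, params, seed=seed)
    return pd.DataFrame({"esr": y})


class TestFit:
    def test_intercept_only_recovers_truth(self):
        truth = GIGParams(mu=12.0, sigma=0.9, nu=-0.4)
        df = _intercept_only_frame(truth, 10_000, seed=3)
        f = fit(df, ModelSpec(mu_terms=(), sigma_terms=()))
        # ML fit attains at least the truth's likelihood on the same data
        from esrref.gig import gig_logpdf
        ll_truth = gig_logpdf(df["esr"].to_numpy(), truth.mu, truth.sigma, truth.nu).sum()
        assert f.loglik >= ll_truth - 1e-6
        assert np.exp(f.coefficients["mu"]["(intercept)"]) == pytest.approx(truth.mu, rel=0.05)
        assert np.exp(f.coefficients["sigma"]["(intercept)"]) == pytest.approx(truth.sigma, rel=0.10)
        assert f.nu == pytest.approx(truth.nu, abs=0.25)

    def test_positive_response_required(self):
        df = pd.DataFrame({"esr": [1.0, -2.0, 3.0]})
        with pytest.raises(InvalidInputError):
            fit(df, ModelSpec(mu_terms=()))

    def test_fitted_parameters_positive(self, linear_fit):
        assert np.all(linear_fit.fitted_mu > 0)
        assert np.all(linear_fit.fitted_sigma > 0)

    def test_collinear_terms_named(self, small_derived):
        df = small_derived.copy()
        df["age_copy"] = df["age"]
        spec = ModelSpec(mu_terms=(Term("age", "linear"), Term("age_copy", "linear")))
        with pytest.raises(InvalidInputError, match="age_copy"):
            fit(df, spec)

    def test_adding_a_term_never_decreases_loglik(self, small_derived):
        base = fit(small_derived, ModelSpec(mu_terms=(Term("sex", "linear"),)))
        bigger = fit(
            small_derived,
            ModelSpec(mu_terms=(Term("sex", "linear"), Term("age", "linear"))),
        )
        assert bigger.loglik >= base.loglik - 1e-6

    def test_row_order_invariance(self, small_derived):
        spec = ModelSpec(mu_terms=(Term("sex", "linear"), Term("age", "linear")))
        a = fit(small_derived, spec)
        shuffled = small_derived.sample(frac=1.0, random_state=1).reset_index(drop=True)
        b = fit(shuffled, spec)
        assert b.loglik == pytest.approx(a.loglik, rel=1e-8)

    def test_smoothing_to_infinity_collapses_to_linear(self, small_derived):
        linear = fit(
            small_derived,
            ModelSpec(mu_terms=(Term("age", "linear"), Term("sex", "linear"))),
        )
        frozen = fit(
            small_derived,
            ModelSpec(
                mu_terms=(Term("age", "pspline"), Term("sex", "linear")),
                n_knots=12, lambda_grid=(1e12,),
            ),
        )
        assert frozen.loglik == pytest.approx(linear.loglik, abs=1e-4)
        assert frozen.edf["mu:age"] == pytest.approx(1.0, abs=0.01)

    def test_small_smoothing_beats_linear_loglik(self, small_derived):
        linear = fit(
            small_derived,
            ModelSpec(mu_terms=(Term("age", "linear"), Term("sex", "linear"))),
        )
        wiggly = fit(
            small_derived,
            ModelSpec(
                mu_terms=(Term("age", "pspline"), Term("sex", "linear")),
                n_knots=12, lambda_grid=(1e-3,),
            ),
        )
        assert wiggly.loglik >= linear.loglik - 1e-6


class TestBIC:
    def test_formula_arithmetic(self, linear_fit):
        stub = FittedModel(
            spec=linear_fit.spec, n=100, coefficients={},
            beta_mu=np.zeros(1), beta_sigma=np.zeros(1), nu=0.0,
            smoothing_lambda=None, loglik=-100.0, penalized_loglik=-100.0,
            edf={}, total_df=3.0, bic=0.0,
            fitted_mu=np.ones(1), fitted_sigma=np.ones(1), response=np.ones(1),
        )
        assert bic(stub) == pytest.approx(200.0 + 3.0 * np.log(100.0), abs=1e-10)

    def test_bic_field_consistent_with_formula(self, linear_fit):
        assert linear_fit.bic == pytest.approx(bic(linear_fit), abs=1e-9)

    def test_more_df_same_loglik_larger_bic(self, linear_fit):
        base = bic(linear_fit)
        import dataclasses
        inflated = dataclasses.replace(linear_fit, total_df=linear_fit.total_df + 2)
        assert bic(inflated) > base


class TestSelect:
    def test_single_candidate_returned(self, small_derived):
        spec = ModelSpec(mu_terms=(Term("sex", "linear"),), name="only")
        best, ranking = select_model(small_derived, [spec])
        assert best.spec.name == "only"
        assert len(ranking) == 1

    def test_ranking_sorted_by_bic(self, small_derived):
        specs = [
            ModelSpec(mu_terms=(), name="null"),
            ModelSpec(mu_terms=(Term("sex", "linear"),), name="sex"),
            ModelSpec(mu_terms=(Term("sex", "linear"), Term("age", "linear")), name="sex+age"),
        ]
        best, ranking = select_model(small_derived, specs)
        assert list(ranking["bic"]) == sorted(ranking["bic"])
        assert best.bic == ranking["bic"].iloc[0]
        # with the default generator both sex and age carry real signal
        assert best.spec.name == "sex+age"

    def test_no_candidates_rejected(self, small_derived):
        with pytest.raises(InvalidInputError):
            select_model(small_derived, [])


class TestQuantileResiduals:
    def test_standard_normal_under_truth(self):
        cfg = recovery_config(seed=31, n_per_stratum=215)
        df = derive_table(simulate_cohort(cfg))
        spec = ModelSpec(
            mu_terms=(Term("age", "linear"), Term("sex", "linear")),
            sigma_terms=(),
        )
        z = quantile_residuals(fit(df, spec))
        assert abs(z.mean()) < 0.05
        assert 0.9 < z.var() < 1.1

    def test_observation_at_fitted_median_gives_zero(self):
        params = GIGParams(mu=10.0, sigma=0.9, nu=-0.4)
        med = float(gig_quantile(0.5, params))
        n = 50
        stub = FittedModel(
            spec=ModelSpec(mu_terms=()), n=n, coefficients={},
            beta_mu=np.zeros(1), beta_sigma=np.zeros(1), nu=params.nu,
            smoothing_lambda=None, loglik=0.0, penalized_loglik=0.0,
            edf={}, total_df=2.0, bic=0.0,
            fitted_mu=np.full(n, params.mu), fitted_sigma=np.full(n, params.sigma),
            response=np.full(n, med),
        )
        z = quantile_residuals(stub)
        np.testing.assert_allclose(z, 0.0, atol=1e-6)

    def test_misspecified_location_shifts_residuals(self):
        # data from mu=20 scored against a model that believes mu=10
        truth = GIGParams(mu=20.0, sigma=0.9, nu=-0.4)
        y = gig_rvs(2000, truth, seed=5)
        stub = FittedModel(
            spec=ModelSpec(mu_terms=()), n=len(y), coefficients={},
            beta_mu=np.zeros(1), beta_sigma=np.zeros(1), nu=-0.4,
            smoothing_lambda=None, loglik=0.0, penalized_loglik=0.0,
            edf={}, total_df=2.0, bic=0.0,
            fitted_mu=np.full(len(y), 10.0), fitted_sigma=np.full(len(y), 0.9),
            response=np.asarray(y),
        )
        z = quantile_residuals(stub)
        assert z.mean() > 0.5


class TestWormPlot:
    def test_null_points_mostly_inside_band(self):
        rng = np.random.default_rng(12)
        w = worm_plot_data(rng.standard_normal(10_000))
        inside = (w["deviation"] >= w["lower"]) & (w["deviation"] <= w["upper"])
        assert inside.mean() >= 0.90

    def test_location_shift_moves_points_up(self):
        rng = np.random.default_rng(13)
        w = worm_plot_data(rng.standard_normal(2000) + 1.0)
        assert (w["deviation"] > 0).mean() > 0.95

    def test_band_shrinks_with_n(self):
        rng = np.random.default_rng(14)
        w_small = worm_plot_data(rng.standard_normal(100))
        w_big = worm_plot_data(rng.standard_normal(10_000))
        # compare half-width at the center of the plot
        mid_small = w_small["upper"].iloc[len(w_small) // 2]
        mid_big = w_big["upper"].iloc[len(w_big) // 2]
        assert mid_big < mid_small / 5.0

    def test_too_few_residuals_rejected(self):
        with pytest.raises(InvalidInputError):
            worm_plot_data(np.zeros(10))

    def test_subsampling_keeps_requested_points(self):
        rng = np.random.default_rng(15)
        w = worm_plot_data(rng.standard_normal(5000), n_points=200)
        assert len(w) == 200
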