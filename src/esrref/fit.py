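"""Penalized-likelihood distributional regression with a GIG response.

The mean ``mu`` and scale ``sigma`` of the Generalized Inverse Gaussian
are each modelled through a log link as an additive predictor in the
covariates; every covariate enters a predictor either as a constant (i.e.
not at all), a linear term, or a penalized cubic B-spline (P-spline).
The shape ``nu`` is a single constant.  All parameters are estimated
jointly by quasi-Newton maximization of the roughness-penalized
log-likelihood; the spline smoothing parameter is chosen by minimizing
BIC over a log-spaced grid, with effective degrees of freedom measured as
the trace of the smoother influence matrix at the converged fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, optimize, stats

from .errors import ConvergenceError, InvalidInputError, MissingDataError
from .gig import gig_cdf_params, gig_logpdf

__all__ = [
    "Term",
    "ModelSpec",
    "FittedModel",
    "fit",
    "bic",
    "select_model",
    "quantile_residuals",
    "worm_plot_data",
]

# fixed dummy-coding level orders for the study's categorical covariates
CATEGORY_LEVELS = {
    "sex": ["female", "male"],
    "smoking_category": ["never", "ex_smoker", "smoker"],
    "alcohol_category": ["abstainer_occasional", "light", "moderate", "heavy"],
    "activity_category": ["low", "moderate", "high"],
    "bmi_class": ["normal", "overweight", "obese"],
}

DEFAULT_LAMBDA_GRID = tuple(np.logspace(6.0, -2.0, 9))  # smooth -> wiggly


@dataclass(frozen=True)
class Term:
    covariate: str
    form: str  # "constant" | "linear" | "pspline"

    def __post_init__(self):
        if self.form not in ("constant", "linear", "pspline"):
            raise InvalidInputError(f"unknown term form: {self.form!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Term structure of the two link-function predictors."""

    mu_terms: tuple
    sigma_terms: tuple = ()
    response: str = "esr"
    mu_link: str = "log"
    sigma_link: str = "log"
    n_knots: int = 20          # interior knots per P-spline
    penalty_order: int = 2
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "mu_terms", tuple(self.mu_terms))
        object.__setattr__(self, "sigma_terms", tuple(self.sigma_terms))
        for terms in (self.mu_terms, self.sigma_terms):
            covs = [t.covariate for t in terms if t.form != "constant"]
            if len(covs) != len(set(covs)):
                raise InvalidInputError("a covariate may appear at most once per predictor")
        if self.mu_link != "log" or self.sigma_link != "log":
            raise InvalidInputError("only the log link is supported for mu and sigma")

    def label(self) -> str:
        if self.name:
            return self.name
        fmt = lambda ts: "+".join(f"{t.covariate}({t.form[0]})" for t in ts) or "1"
        return f"mu~{fmt(self.mu_terms)}; sigma~{fmt(self.sigma_terms)}"


# ---------------------------------------------------------------------------
# term encoders
# ---------------------------------------------------------------------------

class _LinearEncoder:
    """Standardized numeric column; coefficients reported on the raw scale."""

    def __init__(self, cov: str, x: np.ndarray):
        self.cov = cov
        self.center = float(np.mean(x))
        self.scale = float(np.std(x)) or 1.0
        self.names = [cov]
        self.penalized = False

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        x = np.asarray(data[self.cov], dtype=float)
        return ((x - self.center) / self.scale)[:, None]


class _DummyEncoder:
    def __init__(self, cov: str, values: pd.Series):
        self.cov = cov
        levels = CATEGORY_LEVELS.get(cov)
        if levels is None:
            if values.dtype == bool or set(values.unique()) <= {0, 1, True, False}:
                levels = [False, True]
            else:
                levels = sorted(values.astype(str).unique())
        self.levels = list(levels)
        unseen = set(values.astype(str if not isinstance(levels[0], bool) else bool)) - set(self.levels)
        if unseen:
            raise InvalidInputError(f"{cov}: unknown levels {sorted(map(str, unseen))}")
        self.names = [f"{cov}={lv}" for lv in self.levels[1:]]
        self.penalized = False

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        vals = data[self.cov]
        if isinstance(self.levels[0], bool):
            vals = vals.astype(bool)
        else:
            vals = vals.astype(str)
        return np.column_stack([(vals == lv).to_numpy(float) for lv in self.levels[1:]])


class _PSplineEncoder:
    """Cubic B-spline basis, equally spaced knots, sum-to-zero constraint.

    The difference penalty of order ``penalty_order`` acts on the basis
    coefficients; both basis and penalty are projected onto the
    sum-to-zero constraint null space so the spline is identifiable next
    to the intercept.
    """

    degree = 3

    def __init__(self, cov: str, x: np.ndarray, n_knots: int, penalty_order: int):
        self.cov = cov
        self.lo = float(np.min(x))
        self.hi = float(np.max(x))
        if self.hi <= self.lo:
            raise InvalidInputError(f"{cov}: degenerate range for a P-spline")
        h = (self.hi - self.lo) / (n_knots + 1)
        self.knots = self.lo + h * np.arange(-self.degree, n_knots + self.degree + 2)
        nb = len(self.knots) - self.degree - 1
        B = self._basis(x)
        D = np.diff(np.eye(nb), n=penalty_order, axis=0)
        C = B.sum(axis=0, keepdims=True)           # sum-to-zero over training rows
        self.Z = linalg.null_space(C)              # nb x (nb - 1)
        self.penalty = self.Z.T @ (D.T @ D) @ self.Z
        # eigen-decomposition of the penalty for the per-lambda
        # Demmler-Reinsch-style rescaling that keeps the optimization
        # well conditioned at every smoothing level
        s, U = linalg.eigh(self.penalty)
        self.pen_eigvals = np.clip(s, 0.0, None)
        self.pen_eigvecs = U
        self.names = [f"ps({cov})[{j}]" for j in range(self.Z.shape[1])]
        self.penalized = True

    def _basis(self, x: np.ndarray) -> np.ndarray:
        # clip into the open top of the basis support (design_matrix
        # rejects x exactly at the last usable knot)
        xc = np.clip(np.asarray(x, dtype=float), self.lo, np.nextafter(self.hi, self.lo))
        return interpolate.BSpline.design_matrix(
            xc, self.knots, self.degree
        ).toarray()

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        return self._basis(np.asarray(data[self.cov], dtype=float)) @ self.Z


class _PredictorDesign:
    """Intercept plus encoded term blocks for one link predictor."""

    def __init__(self, terms, data: pd.DataFrame, n_knots: int, penalty_order: int):
        self.encoders = []
        for t in terms:
            if t.form == "constant":
                continue
            if t.covariate not in data.columns:
                raise MissingDataError(f"covariate not in data: {t.covariate}")
            col = data[t.covariate]
            if t.form == "linear":
                if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
                    enc = _LinearEncoder(t.covariate, col.to_numpy(float))
                else:
                    enc = _DummyEncoder(t.covariate, col)
            else:  # pspline
                if not pd.api.types.is_numeric_dtype(col) or pd.api.types.is_bool_dtype(col):
                    raise InvalidInputError(f"pspline requires a continuous covariate: {t.covariate}")
                enc = _PSplineEncoder(t.covariate, col.to_numpy(float), n_knots, penalty_order)
            self.encoders.append(enc)
        self.col_names = ["(intercept)"] + [n for e in self.encoders for n in e.names]
        self.n_cols = len(self.col_names)

    def build(self, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        blocks = [np.ones((n, 1))]
        blocks += [e.transform(data) for e in self.encoders]
        return np.concatenate(blocks, axis=1)

    def penalty_matrix(self, lam: float) -> np.ndarray:
        P = np.zeros((self.n_cols, self.n_cols))
        j = 1
        for e in self.encoders:
            k = len(e.names)
            if e.penalized:
                P[j:j + k, j:j + k] = lam * e.penalty
            j += k
        return P

    def reparam(self, lam: float):
        """Coefficient transform T and diagonal penalty for smoothing lam.

        Spline blocks are rotated onto the penalty eigenbasis and scaled
        by 1/sqrt(1 + lam * s_j); in these coordinates the penalty is the
        diagonal lam*s_j/(1 + lam*s_j) <= 1, so the objective's curvature
        stays of likelihood order at every lam.  Original coefficients
        are beta = T @ gamma.
        """
        T = np.eye(self.n_cols)
        pen_diag = np.zeros(self.n_cols)
        j = 1
        for e in self.encoders:
            k = len(e.names)
            if e.penalized:
                scale = 1.0 / np.sqrt(1.0 + lam * e.pen_eigvals)
                T[j:j + k, j:j + k] = e.pen_eigvecs * scale[None, :]
                pen_diag[j:j + k] = lam * e.pen_eigvals * scale**2
            j += k
        return T, pen_diag

    def term_slices(self):
        out = [("(intercept)", slice(0, 1), False)]
        j = 1
        for e in self.encoders:
            k = len(e.names)
            out.append((e.cov, slice(j, j + k), e.penalized))
            j += k
        return out

    @property
    def has_pspline(self) -> bool:
        return any(e.penalized for e in self.encoders)


def _check_rank(X: np.ndarray, names) -> None:
    R = np.linalg.qr(X, mode="r")
    d = np.abs(np.diag(R))
    tol = d.max() * max(X.shape) * np.finfo(float).eps * 1e3
    bad = [names[i] for i in np.where(d < tol)[0]]
    if bad:
        raise InvalidInputError(f"design matrix is rank deficient; collinear terms: {bad}")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    spec: ModelSpec
    n: int
    coefficients: dict            # raw-scale named coefficients per predictor
    beta_mu: np.ndarray           # internal coordinates
    beta_sigma: np.ndarray
    nu: float
    smoothing_lambda: Optional[float]
    loglik: float                 # unpenalized, at the optimum
    penalized_loglik: float
    edf: dict                     # per (predictor, term) effective df
    total_df: float
    bic: float
    fitted_mu: np.ndarray
    fitted_sigma: np.ndarray
    response: np.ndarray
    mu_design: _PredictorDesign = field(repr=False, default=None)
    sigma_design: _PredictorDesign = field(repr=False, default=None)
    n_iter: int = 0

    def predict_params(self, data: pd.DataFrame):
        """Per-row (mu, sigma, nu) for new data."""
        eta_mu = self.mu_design.build(data) @ self.beta_mu
        eta_sigma = self.sigma_design.build(data) @ self.beta_sigma
        return np.exp(eta_mu), np.exp(eta_sigma), np.full(len(data), self.nu)

    def summary_dict(self) -> dict:
        return {
            "model": self.spec.label(),
            "n": int(self.n),
            "coefficients": self.coefficients,
            "nu": float(self.nu),
            "smoothing_lambda": None if self.smoothing_lambda is None else float(self.smoothing_lambda),
            "loglik": float(self.loglik),
            "edf": {k: float(v) for k, v in self.edf.items()},
            "total_df": float(self.total_df),
            "bic": float(self.bic),
        }


def _nll_factory(y, Xmu, Xsig, pdiag_mu, pdiag_sig, h=1e-5):
    """Penalized negative log-likelihood and its gradient.

    The gradient chains an exact design-matrix product onto per-observation
    derivatives of the log-likelihood in the linear predictors (central
    differences, two vectorized evaluations per predictor), so its cost is
    independent of the number of coefficients.
    """
    pmu = Xmu.shape[1]
    psig = Xsig.shape[1]
    trace: list = []

    def unpenalized_loglik(theta):
        eta_mu = np.clip(Xmu @ theta[:pmu], -25.0, 25.0)
        eta_sig = np.clip(Xsig @ theta[pmu:pmu + psig], -10.0, 10.0)
        return gig_logpdf(y, np.exp(eta_mu), np.exp(eta_sig), theta[-1])

    def nll_grad(theta):
        gmu = theta[:pmu]
        gsig = theta[pmu:pmu + psig]
        nu = theta[-1]
        eta_mu = np.clip(Xmu @ gmu, -25.0, 25.0)
        eta_sig = np.clip(Xsig @ gsig, -10.0, 10.0)
        mu = np.exp(eta_mu)
        sig = np.exp(eta_sig)
        ll = gig_logpdf(y, mu, sig, nu)
        if not np.all(np.isfinite(ll)):
            trace.append(1e10)
            return 1e10, np.zeros_like(theta)
        pen = 0.5 * (pdiag_mu @ gmu**2 + pdiag_sig @ gsig**2)
        f = -float(ll.sum()) + pen
        trace.append(f)

        dmu = (
            gig_logpdf(y, np.exp(eta_mu + h), sig, nu)
            - gig_logpdf(y, np.exp(eta_mu - h), sig, nu)
        ) / (2.0 * h)
        dsig = (
            gig_logpdf(y, mu, np.exp(eta_sig + h), nu)
            - gig_logpdf(y, mu, np.exp(eta_sig - h), nu)
        ) / (2.0 * h)
        dnu = float(
            (gig_logpdf(y, mu, sig, nu + h) - gig_logpdf(y, mu, sig, nu - h)).sum()
        ) / (2.0 * h)
        g = np.concatenate([
            -(Xmu.T @ dmu) + pdiag_mu * gmu,
            -(Xsig.T @ dsig) + pdiag_sig * gsig,
            [-dnu],
        ])
        return f, g

    return nll_grad, unpenalized_loglik, trace


def _minimize(nll_grad, theta0, n_params, trace):
    bounds = [(None, None)] * (n_params - 1) + [(-50.0, 50.0)]
    opts = {"maxiter": 2000, "maxfun": 200000, "ftol": 1e-11, "gtol": 1e-6}
    res = optimize.minimize(
        nll_grad, theta0, method="L-BFGS-B", jac=True, bounds=bounds, options=opts
    )
    if not res.success:
        res2 = optimize.minimize(
            nll_grad, res.x, method="L-BFGS-B", jac=True, bounds=bounds, options=opts
        )
        if res2.fun <= res.fun:
            res = res2
    if not np.isfinite(res.fun) or res.fun >= 1e9:
        raise ConvergenceError(
            f"penalized-likelihood optimization failed: {res.message}; "
            f"trace tail={trace[-5:]}"
        )
    return res


def _working_weights(loglik_of_eta, eta, h=1e-4):
    """-d2 loglik_i / d eta_i^2 by central differences, floored at 1e-8."""
    l0 = loglik_of_eta(eta)
    lp = loglik_of_eta(eta + h)
    lm = loglik_of_eta(eta - h)
    w = -(lp - 2.0 * l0 + lm) / h**2
    return np.clip(w, 1e-8, None)


def _predictor_edf(X, w, P):
    """Per-column effective df: diag of (X'WX + P)^-1 X'WX."""
    XtWX = X.T @ (X * w[:, None])
    A = np.linalg.solve(XtWX + P, XtWX)
    return np.diag(A)


def _fit_once(y, data, spec: ModelSpec, lam: Optional[float], start=None):
    mu_design = _PredictorDesign(spec.mu_terms, data, spec.n_knots, spec.penalty_order)
    sigma_design = _PredictorDesign(spec.sigma_terms, data, spec.n_knots, spec.penalty_order)
    Xmu = mu_design.build(data)
    Xsig = sigma_design.build(data)
    _check_rank(Xmu, mu_design.col_names)
    _check_rank(Xsig, sigma_design.col_names)
    Tmu, pdiag_mu = mu_design.reparam(lam or 0.0)
    Tsig, pdiag_sig = sigma_design.reparam(lam or 0.0)
    Pmu = mu_design.penalty_matrix(lam or 0.0)
    Psig = sigma_design.penalty_matrix(lam or 0.0)
    pmu, psig = Xmu.shape[1], Xsig.shape[1]

    nll_grad, loglik_fn, trace = _nll_factory(y, Xmu @ Tmu, Xsig @ Tsig, pdiag_mu, pdiag_sig)
    if start is None:
        theta0 = np.zeros(pmu + psig + 1)
        theta0[0] = np.log(np.mean(y))
        theta0[pmu] = np.log(0.8)
        theta0[-1] = -0.5
    else:
        # warm start given in original coefficient coordinates
        b_mu, b_sig, nu0 = start
        theta0 = np.concatenate([
            np.linalg.solve(Tmu, b_mu), np.linalg.solve(Tsig, b_sig), [nu0]
        ])
    res = _minimize(nll_grad, theta0, pmu + psig + 1, trace)
    theta = res.x

    ll = float(loglik_fn(theta).sum())
    beta_mu = Tmu @ theta[:pmu]
    beta_sigma = Tsig @ theta[pmu:pmu + psig]
    nu = float(theta[-1])

    # effective degrees of freedom from the influence-matrix trace
    eta_mu = Xmu @ beta_mu
    eta_sig = Xsig @ beta_sigma
    w_mu = _working_weights(
        lambda e: gig_logpdf(y, np.exp(np.clip(e, -25, 25)), np.exp(eta_sig), nu), eta_mu
    )
    w_sig = _working_weights(
        lambda e: gig_logpdf(y, np.exp(eta_mu), np.exp(np.clip(e, -10, 10)), nu), eta_sig
    )
    edf_mu_cols = _predictor_edf(Xmu, w_mu, Pmu)
    edf_sig_cols = _predictor_edf(Xsig, w_sig, Psig)

    edf: dict = {}
    for prefix, design, cols in (("mu", mu_design, edf_mu_cols), ("sigma", sigma_design, edf_sig_cols)):
        for name, sl, penalized in design.term_slices():
            val = float(cols[sl].sum()) if penalized else float(sl.stop - sl.start)
            edf[f"{prefix}:{name}"] = val
    total_df = sum(edf.values()) + 1.0  # + nu
    n = len(y)
    bic_val = -2.0 * ll + total_df * np.log(n)

    # raw-scale coefficient reporting
    coefficients = {"mu": {}, "sigma": {}}
    for key, design, beta in (("mu", mu_design, beta_mu), ("sigma", sigma_design, beta_sigma)):
        out = {}
        intercept = beta[0]
        j = 1
        for enc in design.encoders:
            k = len(enc.names)
            if isinstance(enc, _LinearEncoder):
                out[enc.cov] = float(beta[j] / enc.scale)
                intercept -= beta[j] * enc.center / enc.scale
            elif isinstance(enc, _DummyEncoder):
                for name, b in zip(enc.names, beta[j:j + k]):
                    out[name] = float(b)
            j += k
        out["(intercept)"] = float(intercept)
        coefficients[key] = out

    return FittedModel(
        spec=spec, n=n, coefficients=coefficients,
        beta_mu=beta_mu, beta_sigma=beta_sigma, nu=nu,
        smoothing_lambda=lam,
        loglik=ll, penalized_loglik=-float(res.fun),
        edf=edf, total_df=float(total_df), bic=float(bic_val),
        fitted_mu=np.exp(eta_mu), fitted_sigma=np.exp(eta_sig),
        response=np.asarray(y, dtype=float),
        mu_design=mu_design, sigma_design=sigma_design,
        n_iter=int(res.nit),
    ), (beta_mu, beta_sigma, nu)


def fit(data: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Fit the distributional regression defined by ``spec``.

    For specs containing P-spline terms the smoothing parameter is chosen
    by minimizing BIC over ``spec.lambda_grid`` (one shared value across
    spline terms), warm-starting each fit from the previous grid point.
    """
    if spec.response not in data.columns:
        raise MissingDataError(f"response column missing: {spec.response}")
    y = np.asarray(data[spec.response], dtype=float)
    if np.any(y <= 0):
        raise InvalidInputError("response values must be strictly positive")

    probe_mu = _PredictorDesign(spec.mu_terms, data, spec.n_knots, spec.penalty_order)
    probe_sig = _PredictorDesign(spec.sigma_terms, data, spec.n_knots, spec.penalty_order)
    if not (probe_mu.has_pspline or probe_sig.has_pspline):
        fitted, _ = _fit_once(y, data, spec, None)
        return fitted

    # BIC is effectively unimodal along the smoothing grid; walk from
    # smooth to wiggly and stop once it has worsened for two points
    best = None
    start = None
    worse = 0
    for lam in spec.lambda_grid:
        fitted, start = _fit_once(y, data, spec, float(lam), start)
        if best is None or fitted.bic < best.bic:
            best = fitted
            worse = 0
        else:
            worse += 1
            if worse >= 2:
                break
    return best


def bic(fitted: FittedModel) -> float:
    """Bayesian Information Criterion: -2 loglik + df * log(n)."""
    return -2.0 * fitted.loglik + fitted.total_df * np.log(fitted.n)


def select_model(data: pd.DataFrame, candidate_specs) -> tuple[FittedModel, pd.DataFrame]:
    """Fit every candidate and rank by BIC (ties broken by fewer edf)."""
    candidate_specs = list(candidate_specs)
    if not candidate_specs:
        raise InvalidInputError("at least one candidate spec is required")
    fits = []
    errors = []
    for s in candidate_specs:
        try:
            fits.append(fit(data, s))
        except (ConvergenceError, InvalidInputError, MissingDataError) as e:
            errors.append((s.label(), str(e)))
    if not fits:
        raise ConvergenceError(f"all candidate fits failed: {errors}")
    ranking = pd.DataFrame({
        "model": [f.spec.label() for f in fits],
        "loglik": [f.loglik for f in fits],
        "total_df": [f.total_df for f in fits],
        "bic": [f.bic for f in fits],
    }).sort_values(["bic", "total_df"], kind="mergesort").reset_index(drop=True)
    best = min(fits, key=lambda f: (f.bic, f.total_df))
    return best, ranking


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def quantile_residuals(fitted: FittedModel) -> np.ndarray:
    """Normalized quantile residuals Phi^-1(F(y_i; fitted params_i)).

    Cumulative probabilities are clipped to [1/(2n), 1 - 1/(2n)] before
    the normal inverse, so extreme observations stay finite.
    """
    n = fitted.n
    F = gig_cdf_params(fitted.response, fitted.fitted_mu, fitted.fitted_sigma, fitted.nu)
    F = np.clip(F, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    return stats.norm.ppf(F)


def worm_plot_data(residuals, n_points: Optional[int] = None) -> pd.DataFrame:
    """Detrended normal Q-Q coordinates with 95% pointwise bands.

    Columns: ``x`` (theoretical normal quantile), ``deviation`` (ordered
    residual minus x), ``lower``/``upper`` (the +-1.96 *
    sqrt(p(1-p)) / (sqrt(n) * phi(x)) acceptance band).
    """
    z = np.sort(np.asarray(residuals, dtype=float))
    n = len(z)
    if n < 20:
        raise InvalidInputError(f"at least 20 residuals required, got {n}")
    p = (np.arange(1, n + 1) - 0.5) / n
    x = stats.norm.ppf(p)
    band = 1.96 * np.sqrt(p * (1.0 - p)) / (np.sqrt(n) * stats.norm.pdf(x))
    out = pd.DataFrame({
        "x": x, "deviation": z - x, "lower": -band, "upper": band,
    })
    if n_points is not None and n_points < n:
        keep = np.unique(np.linspace(0, n - 1, n_points).round().astype(int))
        out = out.iloc[keep].reset_index(drop=True)
    return out
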