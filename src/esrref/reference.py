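"""Percentile reference curves, cut-point tables and group summaries.

Turns a fitted distributional regression into clinically usable outputs:
percentile curves of the biomarker over age for a covariate profile,
age-and-sex reference tables of upper cut points (90th/95th/97.5th
percentiles), threshold-exceedance counts against laboratory limits, and
median/IQR group summaries with Mann-Whitney rank tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, MissingDataError
from .fit import FittedModel
from .gig import gig_quantile_params

__all__ = [
    "DEFAULT_AGE_BINS",
    "percentile_curve",
    "reference_table",
    "count_exceedances",
    "mann_whitney",
    "group_summaries",
]

# reporting bins: youngest category 18-35, oldest >65
DEFAULT_AGE_BINS = ((18.0, 35.0), (35.0, 50.0), (50.0, 65.0), (65.0, 120.0))
REFERENCE_PS = (0.90, 0.95, 0.975)


def _profile_frame(fitted: FittedModel, sex: str, profile: dict, ages) -> pd.DataFrame:
    """Prediction frame for a covariate profile along an age grid."""
    needed = set()
    for design in (fitted.mu_design, fitted.sigma_design):
        for enc in design.encoders:
            needed.add(enc.cov)
    grid = pd.DataFrame({"age": np.asarray(ages, dtype=float)})
    grid["sex"] = sex
    for cov in sorted(needed - {"age", "sex"}):
        if cov not in profile:
            raise MissingDataError(f"covariate profile missing model covariate: {cov}")
        grid[cov] = profile[cov]
    return grid


def percentile_curve(
    fitted: FittedModel,
    sex: str,
    covariate_profile: dict,
    age_grid,
    p: float,
) -> pd.DataFrame:
    """p-th percentile of the response over an age grid, mm/h.

    Evaluates ``q_p(age) = Q_GIG(p; mu(age, sex, profile), sigma(.), nu)``
    at every grid point.  Returns a tidy frame (sex, age, p, value).
    """
    if not 0.0 < p < 1.0:
        raise InvalidInputError("p must lie strictly in (0, 1)")
    grid = _profile_frame(fitted, sex, covariate_profile, age_grid)
    mu, sigma, nu = fitted.predict_params(grid)
    q = gig_quantile_params(p, mu, sigma, nu)
    return pd.DataFrame({"sex": sex, "age": grid["age"], "p": p, "value": q})


def reference_table(
    fitted: FittedModel,
    cohort: pd.DataFrame,
    age_bins=DEFAULT_AGE_BINS,
    ps=REFERENCE_PS,
    at_midpoint: bool = False,
) -> pd.DataFrame:
    """Age-and-sex reference cut points from a fitted model.

    For each (sex, age-bin) cell the default is the average of the
    member-level predicted p-quantiles over the cell's cohort members.
    With ``at_midpoint`` the quantile is instead evaluated once at the
    bin's midpoint age keeping the other covariates at the cell means
    (approximated by the cell-average linear predictor).

    Empty cells are emitted with n = 0 and missing percentiles, with a
    warning.  Percentiles are reported in mm/h rounded to one decimal.
    """
    lo0 = age_bins[0][0]
    for (a, b), (c, d) in itertools.pairwise(age_bins):
        if b != c:
            raise InvalidInputError("age bins must be contiguous")
    ages = cohort["age"].to_numpy(float)
    if ages.min() < lo0 or ages.max() > age_bins[-1][1]:
        raise InvalidInputError("age bins do not cover the cohort age range")

    mu, sigma, nu = fitted.predict_params(cohort)
    rows = []
    for sex in ("female", "male"):
        for lo, hi in age_bins:
            in_bin = (cohort["sex"] == sex) & (ages > lo if lo != lo0 else ages >= lo) & (ages <= hi)
            idx = np.where(in_bin.to_numpy())[0]
            row = {"sex": sex, "age_low": lo, "age_high": hi, "n": len(idx)}
            if len(idx) == 0:
                warnings.warn(f"empty reference cell: {sex} {lo}-{hi}", stacklevel=2)
                for p in ps:
                    row[f"p{100 * p:g}"] = np.nan
            else:
                for p in ps:
                    if at_midpoint:
                        q = float(gig_quantile_params(
                            p, np.exp(np.log(mu[idx]).mean()),
                            np.exp(np.log(sigma[idx]).mean()), nu[idx[0]],
                        ))
                    else:
                        q = float(np.mean(gig_quantile_params(p, mu[idx], sigma[idx], nu[idx])))
                    row[f"p{100 * p:g}"] = round(q, 1)
            rows.append(row)
    return pd.DataFrame(rows)


def count_exceedances(
    cohort: pd.DataFrame,
    male_threshold: float = 20.0,
    female_threshold: float = 30.0,
) -> tuple[int, float]:
    """Count members whose ESR is strictly above their sex's laboratory
    threshold; returns (count, percent rounded to one decimal)."""
    if "sex" not in cohort.columns or cohort["sex"].isna().any():
        raise MissingDataError("sex is required for exceedance counting")
    if "esr" not in cohort.columns:
        raise MissingDataError("esr column missing")
    thr = np.where(cohort["sex"].to_numpy() == "male", male_threshold, female_threshold)
    count = int((cohort["esr"].to_numpy(float) > thr).sum())
    percent = round(100.0 * count / len(cohort), 1)
    return count, percent


# ---------------------------------------------------------------------------
# Mann-Whitney U from the rank-sum definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MannWhitneyResult:
    u1: float            # U statistic of the first group
    p_value: float
    method: str          # "exact" | "normal"
    alternative: str


def _u_from_ranks(x: np.ndarray, y: np.ndarray) -> float:
    """U of the first sample, using midranks for ties."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)           # midranks
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney(
    x, y, alternative: str = "two-sided", exact_limit: int = 12
) -> MannWhitneyResult:
    """Mann-Whitney U test from the rank-sum definition.

    Exact p-value by full enumeration of group assignments when
    ``n1 + n2 <= exact_limit``; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise InvalidInputError("both groups must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise InvalidInputError(f"unknown alternative: {alternative}")
    u1 = _u_from_ranks(x, y)

    if n1 + n2 <= exact_limit:
        combined = np.concatenate([x, y])
        ranks = stats.rankdata(combined)
        us = np.array([
            ranks[list(c)].sum() - n1 * (n1 + 1) / 2.0
            for c in itertools.combinations(range(n1 + n2), n1)
        ])
        p_le = float(np.mean(us <= u1))
        p_ge = float(np.mean(us >= u1))
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(u1, p, "exact", alternative)

    mean_u = n1 * n2 / 2.0
    combined = np.concatenate([x, y])
    N = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (N * (N - 1.0))
    var_u = n1 * n2 / 12.0 * (N + 1.0 - tie_term)
    if var_u <= 0:
        return MannWhitneyResult(u1, 1.0, "normal", alternative)
    sd = np.sqrt(var_u)
    if alternative == "less":
        z = (u1 - mean_u + 0.5) / sd
        p = float(stats.norm.cdf(z))
    elif alternative == "greater":
        z = (u1 - mean_u - 0.5) / sd
        p = float(stats.norm.sf(z))
    else:
        z = (u1 - mean_u - np.sign(u1 - mean_u) * 0.5) / sd
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = min(1.0, p)
    return MannWhitneyResult(u1, p, "normal", alternative)


def group_summaries(cohort: pd.DataFrame, grouping: str, value: str = "esr") -> pd.DataFrame:
    """Median/IQR summaries of ``value`` per level of ``grouping``.

    For exactly two non-empty levels a Mann-Whitney comparison p-value is
    attached (same value on both rows); with one level the test is
    skipped with a warning, with more than two levels each level is
    compared against the first (reference) level.
    """
    if grouping not in cohort.columns:
        raise MissingDataError(f"grouping column missing: {grouping}")
    from .fit import CATEGORY_LEVELS
    present = [lv for lv, g in cohort.groupby(grouping, observed=True, sort=True) if len(g)]
    canonical = CATEGORY_LEVELS.get(grouping)
    if canonical is not None:
        levels = [lv for lv in canonical if lv in present]
    else:
        levels = present
    groups = {lv: cohort.loc[cohort[grouping] == lv, value].to_numpy(float) for lv in levels}
    rows = []
    for lv in levels:
        v = groups[lv]
        rows.append({
            grouping: lv, "n": len(v),
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
        })
    out = pd.DataFrame(rows)
    if len(levels) < 2:
        warnings.warn("fewer than two non-empty levels; rank test skipped", stacklevel=2)
        out["p_value"] = np.nan
        return out
    if len(levels) == 2:
        res = mann_whitney(groups[levels[0]], groups[levels[1]])
        out["p_value"] = res.p_value
    else:
        ref = groups[levels[0]]
        ps = [np.nan]
        for lv in levels[1:]:
            ps.append(mann_whitney(ref, groups[lv]).p_value)
        out["p_value"] = ps
    return out
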