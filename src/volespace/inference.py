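"""Mixed-model battery linking behavioral scores to space use.

Each response is modelled separately against one behavioral score at a
time (boldness or exploration; the design is too small for both at once)
plus sex, with study site as a random intercept.  Responses are
transformed to approximate normality before a Gaussian LMM: log for
strictly positive sizes/distances/heights, logit for fractions, log1p for
counts; the transform used is recorded per row.  The score's p-value is a
likelihood-ratio test (df = 1) of the model with vs without the score,
and explained variance is reported as marginal/conditional R-squared from
the variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

LOGIT_EPS = 1e-3


def _log(v):
    v = np.asarray(v, float)
    if np.any(v <= 0):
        raise ValueError("log transform needs strictly positive values")
    return np.log(v)


def _logit(v):
    v = np.clip(np.asarray(v, float), LOGIT_EPS, 1 - LOGIT_EPS)
    return np.log(v / (1 - v))


TRANSFORMS = {
    "gaussian(log)": _log,
    "gaussian(logit)": _logit,
    "gaussian(logit/100)": lambda v: _logit(np.asarray(v, float) / 100.0),
    "gaussian(log1p)": lambda v: np.log1p(np.asarray(v, float)),
    "gaussian(identity)": lambda v: np.asarray(v, float),
}

#: Table-layout battery: response column -> transform family label.
DEFAULT_RESPONSES = {
    "home_range_area_m2": "gaussian(log)",
    "core_area_m2": "gaussian(log)",
    "total_distance_m": "gaussian(log)",
    "overlap_95": "gaussian(logit)",
    "overlap_50": "gaussian(logit)",
    "n_trap_centers_95": "gaussian(log1p)",
    "n_trap_centers_50": "gaussian(log1p)",
    "veg_height_95": "gaussian(log)",
    "veg_height_50": "gaussian(log)",
    "ground_cover_95": "gaussian(logit/100)",
    "ground_cover_50": "gaussian(logit/100)",
}


@dataclass
class LinkageResult:
    response: str
    score: str
    estimate: float
    SE: float
    statistic: float      # estimate / SE (z/t)
    chi2: float           # likelihood-ratio statistic for the score term
    df: int
    p: float
    R2_marginal: float
    R2_conditional: float
    family: str
    note: str = ""


def r2_nakagawa(
    var_fixed: float, var_random: float, var_residual: float
) -> dict:
    """Marginal and conditional R-squared from variance components."""
    total = var_fixed + var_random + var_residual
    if total <= 0:
        raise ValueError("zero total variance")
    return {
        "R2_marginal": var_fixed / total,
        "R2_conditional": (var_fixed + var_random) / total,
    }


def _fit_mixed_ml(y, X, groups):
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MixedLM(y, X, groups=groups).fit(reml=False)
    if not np.all(np.isfinite(fit.params)):
        raise RuntimeError("non-finite mixed-model fit")
    return fit


def _ols_loglik(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    s2 = (resid**2).sum() / n
    llf = -0.5 * n * (np.log(2 * np.pi * s2) + 1)
    return beta, resid, s2, llf


def fit_linkage(
    data: pd.DataFrame,
    response: str,
    score: str,
    sex_col: str = "sex",
    site_col: str = "site",
    family: str | None = None,
) -> LinkageResult:
    """Fit one battery row: ``response ~ score + sex + (1 | site)``."""
    family = family or DEFAULT_RESPONSES.get(response, "gaussian(identity)")
    transform = TRANSFORMS[family]

    df = data[[response, score, sex_col, site_col]].dropna()
    y = transform(df[response].to_numpy())
    s = df[score].to_numpy(float)
    sex_m = (df[sex_col].astype(str).to_numpy() == "M").astype(float)
    sites = df[site_col].to_numpy()
    n_sites = len(np.unique(sites))

    cols = [np.ones(len(y)), s]
    if np.ptp(sex_m) > 0:  # drop a single-sex covariate
        cols.append(sex_m)
    X_full = np.column_stack(cols)
    X_red = np.delete(X_full, 1, axis=1)

    note = ""
    if n_sites >= 3:
        try:
            fit = _fit_mixed_ml(y, X_full, sites)
            fit0 = _fit_mixed_ml(y, X_red, sites)
            est, se = float(fit.params[1]), float(fit.bse[1])
            lrt = max(2.0 * (fit.llf - fit0.llf), 0.0)
            var_site = float(np.asarray(fit.cov_re)[0, 0])
            var_resid = float(fit.scale)
            var_fixed = float(np.var(X_full @ fit.params[: X_full.shape[1]]))
        except Exception:
            note = "fallback:fixed-site"
    else:
        note = "fallback:fixed-site"

    if note:
        # fewer than 3 sites (or a singular fit): site as fixed effect
        k = X_full.shape[1]
        dummies = pd.get_dummies(pd.Series(sites), drop_first=True).to_numpy(float)
        Xf = np.column_stack([X_full, dummies])
        Xr = np.column_stack([X_red, dummies])
        beta, resid, s2, llf = _ols_loglik(y, Xf)
        _, _, _, llf0 = _ols_loglik(y, Xr)
        est = float(beta[1])
        n, p_ = Xf.shape
        cov = s2 * n / max(n - p_, 1) * np.linalg.pinv(Xf.T @ Xf)
        se = float(np.sqrt(cov[1, 1]))
        lrt = max(2.0 * (llf - llf0), 0.0)
        var_fixed = float(np.var(Xf[:, :k] @ beta[:k]))
        var_site = float(np.var(Xf[:, k:] @ beta[k:])) if Xf.shape[1] > k else 0.0
        var_resid = float(s2)

    r2 = r2_nakagawa(var_fixed, var_site, var_resid)
    p = float(stats.chi2.sf(lrt, 1))
    return LinkageResult(
        response=response,
        score=score,
        estimate=est,
        SE=se,
        statistic=est / se if se > 0 else np.nan,
        chi2=float(lrt),
        df=1,
        p=p,
        R2_marginal=float(r2["R2_marginal"]),
        R2_conditional=float(r2["R2_conditional"]),
        family=family,
        note=note,
    )


def run_battery(
    data: pd.DataFrame,
    responses: dict | None = None,
    scores: tuple = ("boldness", "exploration"),
    sex_col: str = "sex",
    site_col: str = "site",
) -> pd.DataFrame:
    """Fit the full response x score battery and return the result table.

    ``responses`` maps response column -> family label (defaults to the
    table layout of the field study: sizes, distance, overlap, trapping
    points and microhabitat at both isopleth levels).  Missing response
    columns are reported and skipped; a Benjamini-Hochberg column is
    added for transparency (no correction was applied to decisions).
    """
    responses = responses if responses is not None else DEFAULT_RESPONSES
    missing = [r for r in responses if r not in data.columns]
    if missing:
        warnings.warn(f"responses missing from data and skipped: {missing}")
    scores = tuple(s for s in scores if s in data.columns) or ()
    if not scores:
        warnings.warn("no behavioral score columns present; empty battery")
    rows = []
    for resp, family in responses.items():
        if resp in missing:
            continue
        for score in scores:
            rows.append(
                asdict(
                    fit_linkage(
                        data, resp, score, sex_col=sex_col, site_col=site_col, family=family
                    )
                )
            )
    out = pd.DataFrame(rows)
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    # stable layout regardless of input individual order
    return out.reset_index(drop=True)
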