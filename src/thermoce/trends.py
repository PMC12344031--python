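"""Temporal CTI trend models and the equilibrium regression.

The trend model is a linear mixed model CTI ~ Year * Latitude with a random
site intercept, fitted by REML; terms are tested with type II Wald
chi-square statistics.  The equilibrium regression fits observed on
predicted CTI and tests the departure of the slope from the theoretical
equilibrium value of 1 by an offset construction; a stacked
CTI ~ Latitude * PredictionType model tests whether predicted and observed
CTI diverge along the latitudinal gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "TrendFit",
    "EquilibriumRegressionFit",
    "fit_cti_trend",
    "site_cti_slopes",
    "equilibrium_regression",
    "wald_chi2",
]


def wald_chi2(params: np.ndarray, cov: np.ndarray, idx) -> tuple[float, int, float]:
    """Wald chi-square test that the coefficient block ``idx`` is zero.

    chi2 = b' V^{-1} b over the selected block, df = block size.  With the
    other main effects retained in the model this realises the
    "analysis of deviance type II" contract for each term.
    """
    idx = np.atleast_1d(idx)
    b = params[idx]
    V = cov[np.ix_(idx, idx)]
    chi2 = float(b @ np.linalg.solve(V, b))
    df = int(idx.size)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


@dataclass
class TrendFit:
    """REML mixed-model fit of CTI ~ Year * Latitude + (1 | Site)."""

    params: pd.Series  # on the centred scale; year slope is degC/yr at mean latitude
    se: pd.Series
    cov: np.ndarray
    wald: pd.DataFrame  # term, chi2, df, p (per term plus pooled year terms)
    re_var: float  # site random-intercept variance
    resid_var: float
    singular: bool  # True when the random effect collapsed and OLS was used
    year_mean: float
    lat_mean: float

    def slope_at(self, latitude: float) -> float:
        """Fitted CTI trend (degC/year) at a given latitude."""
        return float(
            self.params["year"] + self.params["year:latitude"] * (latitude - self.lat_mean)
        )


def _design(df: pd.DataFrame, year_mean: float, lat_mean: float) -> np.ndarray:
    yc = df["year"].to_numpy(dtype=float) - year_mean
    lc = df["latitude"].to_numpy(dtype=float) - lat_mean
    return np.column_stack([np.ones(len(df)), yc, lc, yc * lc])


_TERMS = ["intercept", "year", "latitude", "year:latitude"]


def fit_cti_trend(cti_table: pd.DataFrame, reml: bool = True) -> TrendFit:
    """Fit the CTI trend mixed model on a site-year CTI table.

    ``cti_table`` needs columns site_id, year, latitude, cti.  Year and
    latitude are centred before fitting for numerical stability; the year
    coefficient is therefore the trend at the mean latitude and the
    interaction is unaffected.  If the site variance collapses to (near)
    zero the model falls back to ordinary least squares with
    ``singular=True``.
    """
    df = cti_table.dropna(subset=["cti"])
    if df["site_id"].nunique() < 2:
        raise ValueError("need at least 2 sites")
    if (df.groupby("site_id")["year"].nunique() < 2).any():
        raise ValueError("every site needs at least 2 years")

    year_mean = float(df["year"].mean())
    lat_mean = float(df["latitude"].mean())
    X = _design(df, year_mean, lat_mean)
    y = df["cti"].to_numpy(dtype=float)

    singular = False
    re_var = 0.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = sm.MixedLM(y, X, groups=df["site_id"].to_numpy())
            fit = mod.fit(reml=reml, method="lbfgs")
        re_var = float(np.asarray(fit.cov_re)[0, 0])
        resid_var = float(fit.scale)
        params = np.asarray(fit.fe_params)
        cov = np.asarray(fit.cov_params())[:4, :4]
        if not np.isfinite(params).all() or re_var < 1e-10 * resid_var:
            singular = True
    except Exception:
        singular = True

    if singular:
        warnings.warn("singular random-effect variance; using fixed-intercept OLS")
        ols = sm.OLS(y, X).fit()
        params = np.asarray(ols.params)
        cov = np.asarray(ols.cov_params())
        re_var = 0.0
        resid_var = float(ols.scale)

    rows = []
    for name, i in zip(_TERMS[1:], (1, 2, 3)):
        chi2, dfree, p = wald_chi2(params, cov, i)
        rows.append({"term": name, "chi2": chi2, "df": dfree, "p": p})
    chi2, dfree, p = wald_chi2(params, cov, [1, 3])
    rows.append({"term": "year+year:latitude", "chi2": chi2, "df": dfree, "p": p})
    wald = pd.DataFrame(rows)

    se = np.sqrt(np.diag(cov))
    return TrendFit(
        params=pd.Series(params, index=_TERMS),
        se=pd.Series(se, index=_TERMS),
        cov=cov,
        wald=wald,
        re_var=re_var,
        resid_var=resid_var,
        singular=singular,
        year_mean=year_mean,
        lat_mean=lat_mean,
    )


def site_cti_slopes(cti_table: pd.DataFrame, min_years: int = 3) -> pd.DataFrame:
    """Per-site OLS CTI slope (degC/year); NaN below ``min_years`` years."""
    rows = []
    for site, sub in cti_table.dropna(subset=["cti"]).groupby("site_id", sort=True):
        if sub["year"].nunique() < min_years:
            rows.append({"site_id": site, "slope": np.nan, "n_years": sub["year"].nunique()})
            continue
        x = sub["year"].to_numpy(dtype=float)
        y = sub["cti"].to_numpy(dtype=float)
        slope = float(np.polyfit(x - x.mean(), y, 1)[0])
        rows.append({"site_id": site, "slope": slope, "n_years": int(sub["year"].nunique())})
    return pd.DataFrame(rows)


@dataclass
class EquilibriumRegressionFit:
    """OLS of observed on predicted CTI plus the slope-vs-1 and Eq-along-latitude tests."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    f_regression: float  # F for the pred slope (obs ~ pred)
    df_regression: tuple[int, int]
    f_slope_vs_1: float  # offset construction: (obs - pred) ~ pred
    df_slope_vs_1: tuple[int, int]
    p_slope_vs_1: float
    f_interaction: float  # stacked CTI ~ Latitude * PredictionType
    df_interaction: tuple[int, int]
    p_interaction: float
    n_sites: int


def equilibrium_regression(
    cti_obs, cti_pred, latitude
) -> EquilibriumRegressionFit:
    """Regress observed CTI on predicted CTI and test equilibrium.

    The slope-vs-1 test subtracts the prediction as an offset and tests the
    residual slope of (obs - pred) on pred, which is algebraically the test
    of slope = 1 in the untransformed regression.  The stacked model
    CTI ~ Latitude * PredictionType (2n rows) tests whether the
    latitudinal trends of predicted and observed CTI differ.
    """
    obs = np.asarray(cti_obs, dtype=float)
    pred = np.asarray(cti_pred, dtype=float)
    lat = np.asarray(latitude, dtype=float)
    keep = np.isfinite(obs) & np.isfinite(pred) & np.isfinite(lat)
    obs, pred, lat = obs[keep], pred[keep], lat[keep]
    n = obs.size
    if n < 3:
        raise ValueError("need at least 3 sites with both CTI values")
    if np.ptp(pred) == 0:
        raise ValueError("predicted CTI has zero variance")

    X = sm.add_constant(pred)
    main = sm.OLS(obs, X).fit()
    t_pred = main.tvalues[1]

    offset = sm.OLS(obs - pred, X).fit()
    f_slope1 = float(offset.tvalues[1] ** 2)
    if not np.isfinite(f_slope1) and offset.params[1] == 0:
        f_slope1 = 0.0  # zero residuals: slope exactly 1
    p_slope1 = float(stats.f.sf(f_slope1, 1, n - 2))

    stacked = pd.DataFrame(
        {
            "cti": np.concatenate([pred, obs]),
            "latitude": np.concatenate([lat, lat]),
            "is_obs": np.concatenate([np.zeros(n), np.ones(n)]),
        }
    )
    Xs = np.column_stack(
        [
            np.ones(2 * n),
            stacked["latitude"],
            stacked["is_obs"],
            stacked["latitude"] * stacked["is_obs"],
        ]
    )
    sfit = sm.OLS(stacked["cti"].to_numpy(), Xs).fit()
    f_int = float(sfit.tvalues[3] ** 2)
    p_int = float(stats.f.sf(f_int, 1, 2 * n - 4))

    return EquilibriumRegressionFit(
        slope=float(main.params[1]),
        intercept=float(main.params[0]),
        slope_se=float(main.bse[1]),
        intercept_se=float(main.bse[0]),
        f_regression=float(t_pred**2),
        df_regression=(1, n - 2),
        f_slope_vs_1=f_slope1,
        df_slope_vs_1=(1, n - 2),
        p_slope_vs_1=p_slope1,
        f_interaction=f_int,
        df_interaction=(1, 2 * n - 4),
        p_interaction=p_int,
        n_sites=n,
    )
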