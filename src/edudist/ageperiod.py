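"""Age-period mixed model: complete logit-scale prior surface per sex x region.

logit(value) = intercept + trend * (year - 1994) + natural spline in age
(knots at 45 and 65) + random intercept per country-age group (a
country-sex variant of the grouping is available via ``alpha_grouping``).
Predictions provide the Gaussian-process prior mean on the full
location-age-year grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from edudist._utils import expit, logit, natural_spline_basis

YEAR_CENTER = 1994
AP_KNOTS = (45.0, 65.0)


class AgePeriodError(RuntimeError):
    """Raised on rank-deficient or otherwise unfittable age-period designs."""


@dataclass
class APFit:
    """Fitted age-period model for one (sex, region, quantity)."""

    sex: str
    region: str
    quantity: str
    intercept: float
    trend: float
    spline_coefs: np.ndarray
    knots: tuple
    boundary: tuple
    alpha: dict  # group label -> random intercept
    alpha_grouping: str
    resid_var: float
    converged: bool = True
    year_center: float = YEAR_CENTER

    def _group(self, location, age) -> str:
        if self.alpha_grouping == "country_age_sex":
            return f"{location}|{float(age):g}"
        return str(location)

    def predict_logit(self, location, age, year, include_alpha: bool = True):
        age = np.atleast_1d(np.asarray(age, dtype=float))
        year = np.atleast_1d(np.asarray(year, dtype=float))
        basis = natural_spline_basis(age, self.knots, self.boundary)
        out = (self.intercept + self.trend * (year - self.year_center)
               + basis @ self.spline_coefs)
        if include_alpha:
            out = out + np.array([self.alpha.get(self._group(location, a), 0.0) for a in age])
        return out


def _spline_knots(ages: np.ndarray):
    boundary = (float(ages.min()), float(ages.max()))
    knots = tuple(k for k in AP_KNOTS if boundary[0] < k < boundary[1])
    return knots, boundary


def fit_age_period(points: pd.DataFrame, sex: str, region: str, quantity: str,
                   alpha_grouping: str = "country_age_sex") -> APFit:
    """REML fit of the age-period model on logit(value) for one stratum.

    ``points`` may be the full table; rows are filtered to the stratum if
    ``sex``/``region``/``quantity`` columns are present.  Requires >= 30
    points spanning >= 10 years and >= 3 distinct ages.  Falls back to the
    shrinkage-free least-squares limit when the mixed model is degenerate
    (e.g. zero residual variance on noiseless data).
    """
    if alpha_grouping not in ("country_age_sex", "country_sex"):
        raise ValueError("alpha_grouping must be 'country_age_sex' or 'country_sex'")
    df = points
    for col, val in (("sex", sex), ("region", region), ("quantity", quantity)):
        if col in df.columns:
            df = df[df[col] == val]
    df = df.copy()
    if len(df) < 30:
        raise AgePeriodError(f"need >= 30 points for ({sex}, {region}, {quantity}), got {len(df)}")
    if df["year"].max() - df["year"].min() < 10:
        raise AgePeriodError("points must span at least 10 years")
    if df["age"].nunique() < 3:
        raise AgePeriodError("points must cover at least 3 distinct ages")

    ages = df["age"].to_numpy(dtype=float)
    knots, boundary = _spline_knots(ages)
    basis = natural_spline_basis(ages, knots, boundary)
    year_c = df["year"].to_numpy(dtype=float) - YEAR_CENTER
    exog = np.column_stack([np.ones(len(df)), year_c, basis])
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise AgePeriodError("rank-deficient design: year/age covariates are collinear")
    y = logit(df["value"].to_numpy(dtype=float))

    if alpha_grouping == "country_age_sex":
        groups = (df["location_id"].astype(str) + "|"
                  + df["age"].map(lambda a: f"{float(a):g}")).to_numpy()
    else:
        groups = df["location_id"].astype(str).to_numpy()

    n_spline = basis.shape[1]

    def _pack(beta, alpha, resid_var, converged):
        return APFit(sex=sex, region=region, quantity=quantity, intercept=float(beta[0]),
                     trend=float(beta[1]), spline_coefs=np.asarray(beta[2:]),
                     knots=knots, boundary=boundary, alpha=alpha,
                     alpha_grouping=alpha_grouping, resid_var=resid_var, converged=converged)

    try:
        import statsmodels.api as sm

        if np.ptp(y) < 1e-12:
            raise FloatingPointError("constant outcome")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, exog, groups=groups).fit(reml=True, maxiter=200)
        if not np.isfinite(res.fe_params).all():
            raise FloatingPointError("non-finite fixed effects")
        alpha = {g: float(eff.iloc[0]) for g, eff in res.random_effects.items()}
        return _pack(np.asarray(res.fe_params), alpha, float(res.scale), bool(res.converged))
    except Exception:  # noqa: BLE001 - shrinkage-free fallback
        beta, *_ = np.linalg.lstsq(exog, y, rcond=None)
        resid = y - exog @ beta
        alpha = {g: float(r.mean()) for g, r in pd.Series(resid).groupby(groups)}
        resid2 = resid - pd.Series(groups).map(alpha).to_numpy()
        return _pack(beta, alpha, float(np.var(resid2)), False)


def predict_age_period(fit: APFit, grid: pd.DataFrame) -> pd.DataFrame:
    """Prior-mean surface on a (location_id, age, year) grid.

    Adds ``prior_logit`` and ``prior`` (inverse-logit, in (0,1)) columns;
    random intercepts apply for in-sample country-age groups and are 0
    otherwise.
    """
    out = grid.copy()
    preds = np.empty(len(out))
    for i, rec in enumerate(out.itertuples(index=False)):
        preds[i] = fit.predict_logit(rec.location_id, rec.age, rec.year)[0]
    out["prior_logit"] = preds
    out["prior"] = expit(preds)
    out["sex"] = fit.sex
    out["quantity"] = fit.quantity
    return out


def fit_summary_frame(fit: APFit) -> pd.DataFrame:
    """Flat export of fitted terms (term, estimate, grouping)."""
    rows = [("intercept", fit.intercept, "fixed"), ("year_trend", fit.trend, "fixed")]
    rows += [(f"spline_{i}", float(c), "fixed") for i, c in enumerate(fit.spline_coefs)]
    rows += [(f"alpha[{g}]", v, fit.alpha_grouping) for g, v in sorted(fit.alpha.items())]
    return pd.DataFrame(rows, columns=["term", "estimate", "grouping"])
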