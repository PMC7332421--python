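"""Cohort extrapolation: project observed cohorts across ages and years.

Repeat observations of the same birth cohort (both after 1990, at most 10
years apart, both at ages >= 25) yield annualized logit differences.  A
per-survey-pairing bias -- the average annual change for cohorts aged 60-70
between the two waves -- is removed so the average change at 65 is zero.
The corrected differences are modelled with a natural spline in age (knot at
70) plus location-within-super-region random intercepts; accumulated
predicted annual changes then fill target ages forwards and backwards (not
below age 25), with prediction variance growing in the number of accumulated
years.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from edudist._utils import expit, logit, natural_spline_basis
from edudist.hierarchy import Hierarchy

logger = logging.getLogger(__name__)

MAX_YEAR_GAP = 10
MIN_PAIR_YEAR = 1990  # both observations must be after this year
MIN_AGE = 25
BIAS_WINDOW = (60.0, 70.0)
SPLINE_KNOT = 70.0

PAIR_COLUMNS = [
    "quantity", "location_id", "sex", "cohort", "age_x", "age_y", "age_mid",
    "year_x", "year_y", "provider_x", "provider_y", "gap", "y_annual", "pairing",
]


def build_pairs(points: pd.DataFrame) -> pd.DataFrame:
    """All qualifying ordered pairs of repeat cohort observations.

    Within each (quantity, location, sex, birth cohort), every pair of
    observations from distinct survey waves is emitted once, with the later
    observation first in the difference; the logit difference is annualized
    by the year gap.  Pairs more than 10 years apart, not strictly after
    1990, or involving ages below 25 are excluded.
    """
    if len(points) == 0:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    df = points.copy()
    df["cohort"] = df["year"] - df["age"]
    df = df.sort_values(["quantity", "location_id", "sex", "cohort", "year", "provider"],
                        kind="mergesort").reset_index(drop=True)
    quantity = df["quantity"].to_numpy()
    loc = df["location_id"].to_numpy()
    sex = df["sex"].to_numpy()
    cohort = df["cohort"].to_numpy()
    year = df["year"].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)
    provider = df["provider"].to_numpy()
    lv = logit(df["value"].to_numpy(dtype=float))

    group_key = pd.MultiIndex.from_arrays([quantity, loc, sex, cohort])
    codes = pd.factorize(group_key)[0]
    boundaries = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(df)]])

    rows = []
    for s, e in zip(starts, ends):
        if e - s < 2:
            continue
        for j in range(s + 1, e):
            for i in range(s, j):
                if year[j] == year[i]:
                    continue  # same wave year: no elapsed time to model
                gap = year[j] - year[i]
                if gap > MAX_YEAR_GAP:
                    continue
                if year[i] <= MIN_PAIR_YEAR or year[j] <= MIN_PAIR_YEAR:
                    continue
                if age[i] < MIN_AGE or age[j] < MIN_AGE:
                    continue
                pairing = (f"{quantity[s]}|{loc[s]}|{sex[s]}|{provider[j]}@{year[j]:g}"
                           f"~{provider[i]}@{year[i]:g}")
                rows.append((quantity[s], loc[s], sex[s], cohort[s], age[j], age[i],
                             0.5 * (age[j] + age[i]), year[j], year[i], provider[j],
                             provider[i], gap, float(lv[j] - lv[i]) / gap, pairing))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def estimate_survey_bias(pairs: pd.DataFrame) -> pd.DataFrame:
    """Remove the per-pairing inter-wave bias from annualized differences.

    The bias of a survey pairing is the mean annualized change over its
    cohorts observed in the 60-70 age window; subtracting it centers the
    pairing's average change in that window (hence at age 65) at zero.
    Pairings with no 60-70 cohorts get bias 0 with a warning.

    Returns the pairs with ``bias`` and ``y_corr`` columns added.
    """
    out = pairs.copy()
    lo, hi = BIAS_WINDOW
    biases = {}
    for pairing, grp in out.groupby("pairing"):
        window = grp[(grp["age_mid"] >= lo) & (grp["age_mid"] <= hi)]
        if len(window) == 0:
            logger.warning("pairing %s has no cohorts aged 60-70; bias set to 0", pairing)
            biases[pairing] = 0.0
        else:
            biases[pairing] = float(window["y_annual"].mean())
    out["bias"] = out["pairing"].map(biases)
    out["y_corr"] = out["y_annual"] - out["bias"]
    return out


@dataclass
class AgingModelFit:
    """Natural-spline model of annual logit change by age, with nested intercepts."""

    beta: np.ndarray  # intercept + spline coefficients
    knots: tuple
    boundary: tuple
    u_super: dict
    u_location: dict
    resid_var: float
    converged: bool = True

    def _basis(self, ages) -> np.ndarray:
        b = natural_spline_basis(np.atleast_1d(np.asarray(ages, dtype=float)),
                                 self.knots, self.boundary)
        return np.column_stack([np.ones(len(b)), b])

    def predict(self, ages, location=None, super_region=None):
        """Predicted annual logit change at the given ages."""
        pred = self._basis(ages) @ self.beta
        if super_region is not None:
            pred = pred + self.u_super.get(super_region, 0.0)
        if location is not None:
            pred = pred + self.u_location.get(location, 0.0)
        return pred if np.ndim(ages) else float(pred[0])


def fit_aging_model(pairs: pd.DataFrame, hierarchy: Hierarchy) -> AgingModelFit:
    """REML fit of corrected annual change on a natural spline in age (knot 70)
    with location-within-super-region random intercepts.

    Falls back to the shrinkage-free limit (least squares plus group-mean
    intercepts) when the mixed model cannot be estimated, e.g. on noiseless
    synthetic data with zero residual variance.
    """
    if "y_corr" not in pairs.columns:
        raise ValueError("pairs must carry y_corr; run estimate_survey_bias first")
    if len(pairs) < 20:
        raise ValueError(f"need >= 20 pairs, got {len(pairs)}")
    ages = pairs["age_mid"].to_numpy(dtype=float)
    if ages.min() > 35.0 or ages.max() < 70.0:
        raise ValueError(
            f"pairs span ages {ages.min():.0f}-{ages.max():.0f}; need coverage of 25-80")

    df = hierarchy.attach(pairs)
    boundary = (float(ages.min()), float(ages.max()))
    knots = (SPLINE_KNOT,) if boundary[0] < SPLINE_KNOT < boundary[1] else ()
    basis = natural_spline_basis(ages, knots, boundary)
    exog = np.column_stack([np.ones(len(df)), basis])
    y = df["y_corr"].to_numpy(dtype=float)

    if np.ptp(y) < 1e-12:
        # degenerate constant outcome: exact intercept-only solution
        beta = np.zeros(exog.shape[1])
        beta[0] = float(y.mean())
        return AgingModelFit(beta=beta, knots=knots, boundary=boundary,
                             u_super={}, u_location={}, resid_var=0.0)

    import statsmodels.api as sm

    work = pd.DataFrame(exog[:, 1:], columns=[f"b{i}" for i in range(exog.shape[1] - 1)])
    work["y"] = y
    work["super_region"] = df["super_region"].to_numpy()
    work["location_id"] = df["location_id"].to_numpy()
    fixed = "y ~ " + " + ".join(c for c in work.columns if c.startswith("b"))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import statsmodels.formula.api as smf

            model = smf.mixedlm(fixed, work, groups="super_region", re_formula="1",
                                vc_formula={"loc": "0 + C(location_id)"})
            res = model.fit(reml=True, maxiter=200)
        beta = np.asarray(res.fe_params)
        u_super, u_location = {}, {}
        for sr, effects in res.random_effects.items():
            for name, value in effects.items():
                if name.startswith("loc["):
                    level = name[name.rindex("[") + 1 : name.rindex("]")]
                    u_location[level] = float(value)
                else:
                    u_super[sr] = float(value)
        return AgingModelFit(beta=beta, knots=knots, boundary=boundary, u_super=u_super,
                             u_location=u_location, resid_var=float(res.scale),
                             converged=bool(res.converged))
    except Exception:  # noqa: BLE001 - fall back to the shrinkage-free limit
        beta, *_ = np.linalg.lstsq(exog, y, rcond=None)
        resid = y - exog @ beta
        u_super = {sr: float(r.mean()) for sr, r in
                   pd.Series(resid).groupby(df["super_region"].to_numpy())}
        resid2 = resid - df["super_region"].map(u_super).to_numpy()
        u_location = {loc: float(r.mean()) for loc, r in
                      pd.Series(resid2).groupby(df["location_id"].to_numpy())}
        resid3 = resid2 - df["location_id"].map(u_location).to_numpy()
        return AgingModelFit(beta=beta, knots=knots, boundary=boundary, u_super=u_super,
                             u_location=u_location, resid_var=float(np.var(resid3)),
                             converged=False)


EXTRAP_COLUMNS = [
    "quantity", "location_id", "sex", "age", "year", "provider", "value", "se",
    "origin_provider", "origin_age", "origin_year", "accumulated_years",
]


def extrapolate_cohort(
    points: pd.DataFrame,
    fit: AgingModelFit,
    target_ages,
    year_range: tuple,
    hierarchy: Hierarchy = None,
) -> pd.DataFrame:
    """Fill target ages/years for each cohort observation (the P'' series).

    Predicted annual logit changes (evaluated at year midpoints, so
    a -> b -> c telescopes exactly to a -> c) are accumulated from the
    observed age to each target age, forwards and backwards; targets below
    age 25 or outside ``year_range`` are skipped.  The extrapolated SE
    combines the source SE with accumulated model error.
    """
    target_ages = sorted(float(a) for a in target_ages)
    y0, y1 = year_range
    src = points[points["age"] >= MIN_AGE]
    if len(src) < len(points):
        logger.warning("dropping %d source points below age %d", len(points) - len(src), MIN_AGE)
    rows = []
    for rec in src.to_dict("records"):
        age0 = float(rec["age"])
        lv0 = float(logit(rec["value"]))
        sr = hierarchy.super_region_of(rec["location_id"]) if hierarchy is not None else None
        for age in target_ages:
            if age < MIN_AGE:
                continue
            year = rec["year"] + (age - age0)
            if not (y0 <= year <= y1):
                continue
            t = age - age0
            if t == 0:
                value, n_steps = rec["value"], 0
            else:
                lo, hi = (age0, age) if t > 0 else (age, age0)
                mids = np.arange(lo + 0.5, hi, 1.0)
                delta = float(np.sum(fit.predict(mids, location=rec["location_id"],
                                                 super_region=sr)))
                value = float(expit(lv0 + np.sign(t) * delta))
                n_steps = len(mids)
            se = float(np.sqrt(rec["se"] ** 2 + n_steps * fit.resid_var))
            rows.append({
                "quantity": rec["quantity"], "location_id": rec["location_id"],
                "sex": rec["sex"], "age": age, "year": year, "provider": rec["provider"],
                "value": value, "se": se, "origin_provider": rec["provider"],
                "origin_age": age0, "origin_year": rec["year"], "accumulated_years": n_steps,
            })
    return pd.DataFrame(rows, columns=EXTRAP_COLUMNS)
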