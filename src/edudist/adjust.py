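"""Inter-provider bias adjustment against regional and location gold standards.

Per region and quantity, a linear mixed model on the logit scale estimates a
random intercept per data provider plus nested location:provider intercepts.
Every non-gold provider's values are shifted by the difference between the
gold standard's random effect and its own; in locations where the gold
provider itself has data, the nested effects are applied in the same
fashion.  Standard errors pass through unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from edudist._utils import expit, logit
from edudist.hierarchy import Hierarchy

logger = logging.getLogger(__name__)

QUANTITIES = ("mean18", "prop_zero")

POINT_COLUMNS = ["quantity", "location_id", "age", "sex", "year", "provider", "value", "se"]

#: floor on standard errors (no-noise simulations report infinite sample size)
SE_FLOOR = 1e-3

_YEAR_CENTER = 1994


def points_from_observations(obs_df: pd.DataFrame) -> pd.DataFrame:
    """Collapse 19-bin observations to the two modelled scalar summaries.

    Each observation row yields two QuantityPoint rows: ``mean18``
    (mean years / 18) and ``prop_zero``, with binomial/delta-method
    standard errors shrinking with effective sample size.
    """
    pcols = [f"p{k}" for k in range(19)]
    bins = obs_df[pcols].to_numpy(dtype=float)
    years = np.arange(19.0)
    means = bins @ years
    sd_years = np.sqrt(np.clip(bins @ years**2 - means**2, 0.0, None))
    p0 = bins[:, 0]
    n = obs_df["n_eff"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_mean = np.where(np.isfinite(n), sd_years / np.sqrt(n) / 18.0, 0.0)
        se_p0 = np.where(np.isfinite(n), np.sqrt(np.clip(p0 * (1 - p0), 0, None) / n), 0.0)
    base = obs_df[["location_id", "provider", "year", "sex"]].copy()
    base["age"] = 0.5 * (obs_df["age_lo"].to_numpy() + obs_df["age_hi"].to_numpy())
    rows = []
    for quantity, value, se in (("mean18", means / 18.0, se_mean), ("prop_zero", p0, se_p0)):
        part = base.copy()
        part["quantity"] = quantity
        part["value"] = np.clip(value, 1e-4, 1 - 1e-4)
        part["se"] = np.maximum(se, SE_FLOOR)
        rows.append(part)
    return pd.concat(rows, ignore_index=True)[POINT_COLUMNS]


@dataclass(frozen=True)
class GoldMap:
    """Gold-standard provider per region, optionally overridden per location."""

    region_gold: dict
    location_gold: dict = field(default_factory=dict)

    def for_region(self, region) -> str:
        try:
            return self.region_gold[region]
        except KeyError:
            raise KeyError(f"no gold-standard provider for region {region!r}") from None

    def for_location(self, location, region) -> str:
        return self.location_gold.get(location, self.for_region(region))

    @classmethod
    def from_csv(cls, path, hierarchy: Hierarchy) -> "GoldMap":
        df = pd.read_csv(path, header=None, names=["entity", "provider"])
        regions = set(hierarchy.regions)
        region_gold, location_gold = {}, {}
        for entity, provider in zip(df["entity"], df["provider"]):
            (region_gold if entity in regions else location_gold)[entity] = provider
        return cls(region_gold=region_gold, location_gold=location_gold)

    def to_csv(self, path) -> None:
        rows = [*self.region_gold.items(), *self.location_gold.items()]
        pd.DataFrame(rows).to_csv(path, index=False, header=False)


@dataclass
class BiasModelFit:
    """Fitted bias model for one (region, quantity)."""

    region: str
    quantity: str
    fixed_effects: pd.Series
    u_provider: dict
    u_location_provider: dict  # (location_id, provider) -> effect
    observed: set  # (location_id, provider) combinations present in the data
    resid_var: float
    converged: bool
    vc_trace: dict = field(default_factory=dict)


class BiasModelError(RuntimeError):
    """Raised on degenerate designs or non-convergent bias-model fits."""

    def __init__(self, message, vc_trace=None):
        super().__init__(message)
        self.vc_trace = vc_trace or {}


def _fallback_effects(df: pd.DataFrame):
    """Shrinkage-free limit of the bias model.

    Least squares with a saturated location x provider cell effect (plus the
    continuous covariates), decomposed by two-way means into provider
    effects and nested location:provider effects.  Used when REML does not
    converge (e.g. provider variance on the boundary with few providers, or
    zero residual variance on noiseless data).
    """
    cells = pd.get_dummies(df["locprov"], dtype=float)
    x = np.column_stack([df[["age_c", "female", "year_c"]].to_numpy(dtype=float),
                         cells.to_numpy()])
    beta, *_ = np.linalg.lstsq(x, df["lv"].to_numpy(), rcond=None)
    cell_eff = dict(zip(cells.columns, beta[3:]))
    mat = {}
    for label, eff in cell_eff.items():
        loc, _, prov = label.rpartition(":")
        mat.setdefault(prov, {})[loc] = eff
    providers = sorted(mat)
    col_mean = {p: float(np.mean(list(mat[p].values()))) for p in providers}
    grand = float(np.mean(list(col_mean.values())))
    u_provider = {p: col_mean[p] - grand for p in providers}
    u_locprov = {}
    locs = sorted({loc for p in mat for loc in mat[p]})
    row_mean = {l: float(np.mean([mat[p][l] for p in providers if l in mat[p]])) for l in locs}
    for p in providers:
        for l, eff in mat[p].items():
            u_locprov[(l, p)] = eff - row_mean[l] - col_mean[p] + grand
    resid = df["lv"].to_numpy() - x @ beta
    fixed = pd.Series(beta[:3], index=["age_c", "female", "year_c"])
    return fixed, u_provider, u_locprov, float(np.var(resid))


def fit_bias_model(points: pd.DataFrame, region: str, quantity: str,
                   hierarchy: Hierarchy = None) -> BiasModelFit:
    """REML mixed model: logit(value) ~ age + sex + location + year
    + (1 | provider) + (1 | location:provider), for one region and quantity.

    Falls back to the shrinkage-free least-squares limit when REML does not
    converge; a :class:`BiasModelError` carrying the variance-component
    trace is raised only when neither estimator is available.
    """
    df = points
    if "region" not in df.columns:
        if hierarchy is None:
            raise ValueError("points need a region column or a hierarchy")
        df = hierarchy.attach(df)
    df = df[(df["region"] == region) & (df["quantity"] == quantity)].copy()
    if len(df) < 10:
        raise ValueError(f"need >= 10 points in region {region!r}, got {len(df)}")
    providers = sorted(df["provider"].unique())
    if len(providers) < 2:
        raise BiasModelError(
            f"region {region!r} has a single provider; provider effects are not identifiable")

    df["lv"] = logit(df["value"].to_numpy())
    df["female"] = (df["sex"] == "female").astype(float)
    df["age_c"] = df["age"] - df["age"].mean()
    df["year_c"] = df["year"] - _YEAR_CENTER
    df["locprov"] = df["location_id"].astype(str) + ":" + df["provider"].astype(str)

    observed = set(zip(df["location_id"], df["provider"]))
    n_loc = df["location_id"].nunique()
    fixed = "lv ~ age_c + female + year_c" + (" + C(location_id)" if n_loc > 1 else "")
    res, failure = None, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(fixed, df, groups="provider", re_formula="1",
                            vc_formula={"locprov": "0 + C(locprov)"})
        try:
            res = model.fit(reml=True, maxiter=200)
            if not (res.converged and np.isfinite(res.fe_params).all()):
                failure = "REML did not converge"
                res = None
        except Exception as exc:  # noqa: BLE001
            failure, res = str(exc), None

    if res is None:
        logger.warning("bias model for (%s, %s): %s; using shrinkage-free fallback",
                       region, quantity, failure)
        try:
            fe, u_provider, u_locprov, resid_var = _fallback_effects(df)
        except Exception as exc:  # noqa: BLE001
            raise BiasModelError(
                f"bias model failed for ({region}, {quantity}): {failure}; "
                f"fallback also failed: {exc}") from exc
        return BiasModelFit(region=region, quantity=quantity, fixed_effects=fe,
                            u_provider=u_provider, u_location_provider=u_locprov,
                            observed=observed, resid_var=resid_var, converged=False,
                            vc_trace={"failure": failure})

    u_provider, u_locprov = {}, {}
    for prov, effects in res.random_effects.items():
        for name, value in effects.items():
            if name.startswith("locprov["):
                level = name[name.rindex("[") + 1 : name.rindex("]")]
                loc, _, p = level.rpartition(":")
                u_locprov[(loc, p)] = float(value)
            else:
                u_provider[prov] = float(value)
    # shrinkage centering within each grouping
    if u_provider:
        c = np.mean(list(u_provider.values()))
        u_provider = {k: v - c for k, v in u_provider.items()}
    vc_trace = {"scale": float(res.scale), "cov_re": float(np.asarray(res.cov_re).ravel()[0])}
    return BiasModelFit(region=region, quantity=quantity, fixed_effects=res.fe_params,
                        u_provider=u_provider, u_location_provider=u_locprov,
                        observed=observed, resid_var=float(res.scale),
                        converged=True, vc_trace=vc_trace)


def apply_adjustment(points: pd.DataFrame, fit: BiasModelFit, gold_map: GoldMap,
                     hierarchy: Hierarchy = None) -> pd.DataFrame:
    """Shift every non-gold point toward the gold standard on the logit scale.

    Regional shift: u_gold - u_provider.  In locations where the gold
    provider has data, additionally u_location:gold - u_location:provider.
    Gold-standard points and points from providers unknown to the fit pass
    through unchanged (the latter with a warning).  SEs are unchanged.
    """
    df = points
    if "region" not in df.columns:
        if hierarchy is None:
            raise ValueError("points need a region column or a hierarchy")
        df = hierarchy.attach(df)
    out = df.copy()
    mask = (out["region"] == fit.region) & (out["quantity"] == fit.quantity)
    gold = gold_map.for_region(fit.region)
    if gold not in fit.u_provider:
        raise BiasModelError(f"gold provider {gold!r} absent from fit for {fit.region!r}")

    locations_with_gold = {loc for (loc, prov) in fit.observed if prov == gold}

    values = out.loc[mask, "value"].to_numpy(dtype=float).copy()
    rows = out.loc[mask, ["location_id", "provider"]].reset_index(drop=True)
    for i, (loc, prov) in enumerate(zip(rows["location_id"], rows["provider"])):
        loc_gold = gold_map.for_location(loc, fit.region)
        if prov == loc_gold:
            continue
        if prov not in fit.u_provider:
            logger.warning("provider %r absent from bias fit (%s, %s); passing through",
                           prov, fit.region, fit.quantity)
            continue
        shift = fit.u_provider[gold] - fit.u_provider[prov]
        if loc in locations_with_gold:
            shift += (fit.u_location_provider.get((loc, loc_gold), 0.0)
                      - fit.u_location_provider.get((loc, prov), 0.0))
        values[i] = float(expit(logit(values[i]) + shift))
    out.loc[mask, "value"] = values
    return out
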