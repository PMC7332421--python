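"""Pipeline orchestration: simulate -> adjust -> cohort -> age-period -> GPR
-> ensemble -> forecast -> metrics, with draw propagation, an out-of-sample
validation harness, and CSV stage interfaces.

All randomness flows from the single configured seed; stage seeds are
derived deterministically from it.  Every stage logs rows in/out and wall
time, and each stage can be re-run from its predecessor's CSV alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from edudist import adjust as adjust_mod
from edudist import ageperiod as ap_mod
from edudist import cohort as cohort_mod
from edudist import ensemble as ens_mod
from edudist import forecast as fc_mod
from edudist import gpr as gpr_mod
from edudist import metrics as metrics_mod
from edudist import synthetic as syn_mod
from edudist._utils import BIN_YEARS, N_BINS, derive_seed, expit, logit
from edudist.hierarchy import Hierarchy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline settings; defaults give the desk-scale synthetic scenario."""

    seed: int = 0
    # world
    n_super: int = 3
    n_regions_per: int = 2
    n_countries_per: int = 2
    year_start: int = 1970
    year_end: int = 2018
    horizon_year: int = 2030
    # survey simulation
    survey_age_lo: int = 25
    survey_age_hi: int = 79
    age_group_width: int = 5
    n_eff: float = 1000.0
    no_noise: bool = False
    bias_scale: float = 0.35
    gold_period: int = 10
    other_period: int = 5
    # estimation
    ages: tuple = (27.0, 32.0, 37.0)  # age-group midpoints, width 5
    alpha_grouping: str = "country_age_sex"
    # hyperparameters (printed defaults)
    k: int = 80
    p_age: float = 0.25
    p_cohort: float = 0.85
    p_space: float = 0.7
    psi: float = 2.5
    loess_span: float = 0.5
    nu: float = 2.0
    length_scale: float = 40.0
    n_draws: int = 1000
    # validation
    holdout_fraction: float = 0.2

    def __post_init__(self):
        if not (0 < self.holdout_fraction <= 0.5):
            raise ValueError("holdout_fraction must be in (0, 0.5]")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def ensemble_config(self) -> ens_mod.EnsembleConfig:
        return ens_mod.EnsembleConfig(k=self.k, p_age=self.p_age, p_cohort=self.p_cohort,
                                      p_space=self.p_space, psi=self.psi,
                                      loess_span=self.loess_span)

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps({f.name: getattr(self, f.name) for f in fields(self)},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in types:
                    raise KeyError(f"unknown config key {key!r}")
                default = getattr(defaults, key)
                if isinstance(default, bool):
                    kwargs[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    kwargs[key] = int(raw)
                elif isinstance(default, float):
                    kwargs[key] = float(raw)
                elif isinstance(default, tuple):
                    kwargs[key] = tuple(float(x) for x in raw.split(","))
                else:
                    kwargs[key] = raw
        return cls(**kwargs)


def _stage(name):
    """Decorator logging rows in/out and wall time per stage."""

    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            n = len(out) if hasattr(out, "__len__") else "-"
            logger.info("stage=%s rows_out=%s wall_s=%.2f", name, n, time.perf_counter() - t0)
            return out

        inner.__name__ = fn.__name__
        inner.__doc__ = fn.__doc__
        return inner

    return wrap


# ---------------------------------------------------------------------------
# stage 1: simulation


GOLD_PROVIDER = "census"
OTHER_PROVIDER = "hhsurvey"


@_stage("simulate")
def simulate_scenario(config: RunConfig):
    """Generate the synthetic world and sparse, biased, noisy surveys.

    Per region: one unbiased gold-standard provider on a sparse decennial
    cycle and one biased provider on a denser cycle, with region-specific
    logit biases.  Returns (hierarchy, truth, observations frame, gold map).
    """
    hierarchy, truth = syn_mod.make_world(
        config.n_super, config.n_regions_per, config.n_countries_per,
        (config.year_start, config.year_end), derive_seed(config.seed, "world"))
    rng = np.random.default_rng(derive_seed(config.seed, "providers"))
    ages = tuple(range(config.survey_age_lo, config.survey_age_hi + 1))
    observations = []
    for region in hierarchy.regions:
        locs = hierarchy.countries_in_region(region)
        gold_years = tuple(range(config.year_start + 5 + int(rng.integers(0, 5)),
                                 config.year_end + 1, config.gold_period))
        other_years = tuple(range(1991 + int(rng.integers(0, 4)),
                                  config.year_end + 1, config.other_period))
        sign = rng.choice([-1.0, 1.0])
        specs = [
            syn_mod.ProviderSpec(name=GOLD_PROVIDER, years=gold_years, locations=locs,
                                 age_group_width=config.age_group_width,
                                 n_eff=config.n_eff, no_noise=config.no_noise, gold=True),
            syn_mod.ProviderSpec(name=OTHER_PROVIDER,
                                 bias_mean18=sign * config.bias_scale * rng.uniform(0.6, 1.0),
                                 bias_p0=-sign * config.bias_scale * rng.uniform(0.6, 1.0),
                                 years=other_years, locations=locs,
                                 age_group_width=config.age_group_width,
                                 n_eff=config.n_eff, no_noise=config.no_noise),
        ]
        for spec in specs:
            observations.extend(syn_mod.simulate_survey(
                truth, spec, derive_seed(config.seed, "survey", region, spec.name), ages=ages))
    obs_df = syn_mod.observations_to_frame(observations)
    gold_map = adjust_mod.GoldMap(region_gold={r: GOLD_PROVIDER for r in hierarchy.regions})
    return hierarchy, truth, obs_df, gold_map


# ---------------------------------------------------------------------------
# stages 2-6: scalar-summary estimation (shared with the validation harness)


@_stage("adjust")
def adjust_points(points: pd.DataFrame, hierarchy: Hierarchy,
                  gold_map: adjust_mod.GoldMap, fits: dict = None) -> pd.DataFrame:
    """Fit (or reuse) per-region bias models and shift all points to gold.

    ``fits`` maps (region, quantity) -> BiasModelFit; when supplied the
    models are not refit (used to adjust held-out data with training fits).
    """
    points = hierarchy.attach(points)
    out = points
    for region in hierarchy.regions:
        for quantity in adjust_mod.QUANTITIES:
            if fits is not None and (region, quantity) in fits:
                fit = fits[(region, quantity)]
            else:
                fit = adjust_mod.fit_bias_model(points, region, quantity)
                if fits is not None:
                    fits[(region, quantity)] = fit
            out = adjust_mod.apply_adjustment(out, fit, gold_map)
    return out


@_stage("cohort")
def cohort_extrapolate(adjusted: pd.DataFrame, hierarchy: Hierarchy,
                       config: RunConfig) -> pd.DataFrame:
    """Pairs -> inter-wave bias correction -> aging model -> P'' series."""
    pairs = cohort_mod.build_pairs(adjusted)
    parts = []
    for quantity in adjust_mod.QUANTITIES:
        qpairs = pairs[pairs["quantity"] == quantity]
        qpoints = adjusted[adjusted["quantity"] == quantity]
        if len(qpairs) >= 20:
            qpairs = cohort_mod.estimate_survey_bias(qpairs)
            fit = cohort_mod.fit_aging_model(qpairs, hierarchy)
        else:
            logger.warning("too few cohort pairs for %s; assuming stable cohorts", quantity)
            fit = cohort_mod.AgingModelFit(beta=np.zeros(2), knots=(), boundary=(25.0, 95.0),
                                           u_super={}, u_location={}, resid_var=0.0)
        parts.append(cohort_mod.extrapolate_cohort(
            qpoints, fit, config.ages, (config.year_start, config.year_end), hierarchy))
    return pd.concat(parts, ignore_index=True)


@_stage("ageperiod")
def fit_priors(extrapolated: pd.DataFrame, hierarchy: Hierarchy,
               config: RunConfig) -> pd.DataFrame:
    """Prior-mean surface on the full estimation grid, per sex x region x quantity."""
    pts = hierarchy.attach(extrapolated)
    grids = []
    for region in hierarchy.regions:
        locs = hierarchy.countries_in_region(region)
        grid = pd.DataFrame(
            [(l, a, y) for l in locs for a in config.ages for y in config.years],
            columns=["location_id", "age", "year"])
        for sex in syn_mod.SEXES:
            for quantity in adjust_mod.QUANTITIES:
                fit = ap_mod.fit_age_period(pts, sex, region, quantity,
                                            alpha_grouping=config.alpha_grouping)
                grids.append(ap_mod.predict_age_period(fit, grid))
    return pd.concat(grids, ignore_index=True)


@_stage("gpr")
def gpr_smooth(extrapolated: pd.DataFrame, prior: pd.DataFrame, hierarchy: Hierarchy,
               config: RunConfig):
    """GP-smooth prior residuals per location-age-sex-quantity series.

    Returns (posterior long frame, draws dict keyed by
    (location, age, sex, quantity) -> (n_draws, n_years) logit-scale array).
    """
    pts = hierarchy.attach(extrapolated)
    pts = pts.copy()
    pts["value_logit"] = logit(pts["value"].to_numpy())
    prior_idx = prior.set_index(["location_id", "age", "sex", "quantity"]).sort_index()

    # amplitude pools: residuals of data points from the prior mean
    prior_lookup = prior.set_index(["location_id", "age", "sex", "quantity", "year"])[
        "prior_logit"]
    keyed = pts.set_index(["location_id", "age", "sex", "quantity", "year"]).index
    pts["resid"] = pts["value_logit"].to_numpy() - prior_lookup.reindex(keyed).to_numpy()
    amplitude = gpr_mod.estimate_amplitude(pts.dropna(subset=["resid"]))

    years = config.years.astype(float)
    rows, draws = [], {}
    for (loc, age, sex, quantity), grp in prior.groupby(
            ["location_id", "age", "sex", "quantity"], sort=True):
        grp = grp.sort_values("year")
        data = pts[(pts["location_id"] == loc) & (pts["age"] == age)
                   & (pts["sex"] == sex) & (pts["quantity"] == quantity)]
        sr = hierarchy.super_region_of(loc)
        cfg = gpr_mod.GPRConfig(nu=config.nu, length_scale=config.length_scale,
                                amplitude=max(amplitude.get((sr, sex), 0.0), 1e-6),
                                n_draws=config.n_draws,
                                seed=derive_seed(config.seed, "gpr", loc, age, sex, quantity))
        post = gpr_mod.gpr_posterior(
            years, grp["prior_logit"].to_numpy(), data["year"].to_numpy(dtype=float),
            data["value_logit"].to_numpy(), data["se"].to_numpy() ** 2, cfg)
        draws[(loc, age, sex, quantity)] = post.draws
        for i, y in enumerate(years):
            rows.append({"location_id": loc, "age": age, "sex": sex, "quantity": quantity,
                         "year": int(y), "prior_logit": post.prior_mean[i],
                         "post_logit": post.posterior_mean[i], "post_sd": post.posterior_sd[i],
                         "post_value": float(expit(post.posterior_mean[i]))})
    return pd.DataFrame(rows), draws


def estimate_summaries(obs_df: pd.DataFrame, hierarchy: Hierarchy,
                       gold_map: adjust_mod.GoldMap, config: RunConfig):
    """Stages 2-6: observations -> GPR posterior of the two scalar summaries."""
    points = adjust_mod.points_from_observations(obs_df)
    bias_fits: dict = {}
    adjusted = adjust_points(points, hierarchy, gold_map, fits=bias_fits)
    extrapolated = cohort_extrapolate(adjusted, hierarchy, config)
    prior = fit_priors(extrapolated, hierarchy, config)
    posterior, draws = gpr_smooth(extrapolated, prior, hierarchy, config)
    return {"points": points, "adjusted": adjusted, "extrapolated": extrapolated,
            "prior": prior, "posterior": posterior, "draws": draws,
            "bias_fits": bias_fits}


# ---------------------------------------------------------------------------
# stages 7-8: distributions


@_stage("ensemble")
def reconstruct_distributions(obs_df: pd.DataFrame, draws: dict, hierarchy: Hierarchy,
                              config: RunConfig) -> dict:
    """Per-draw KNN reconstruction: (location, age, sex) -> (draws, years, 19)."""
    library = ens_mod.build_library(obs_df)
    ens_cfg = config.ensemble_config()
    cells = sorted({(l, a, s) for (l, a, s, _) in draws})
    out = {}
    for (loc, age, sex) in cells:
        d_mean = draws[(loc, age, sex, "mean18")]
        d_p0 = draws[(loc, age, sex, "prop_zero")]
        n_draws = d_mean.shape[0]
        arr = np.empty((n_draws, len(config.years), N_BINS))
        for d in range(n_draws):
            feats = np.column_stack([d_mean[d], d_p0[d]])
            arr[d] = ens_mod.reconstruct_series(feats, config.years, age, loc,
                                                library, hierarchy, ens_cfg)
        out[(loc, age, sex)] = arr
    return out


@_stage("forecast")
def forecast_distributions(dists: dict, config: RunConfig) -> dict:
    """Extend each cell's distribution draws to the horizon year.

    The ROC model applies from each age group's staged start year (2019 for
    25-29, 2024 for 30-34, 2029 for 35-40); earlier forecast years are
    filled by carrying stable cohorts forward from the 2018 estimates,
    interpolating over the age grid.
    """
    years_est = config.years
    years_all = np.arange(config.year_start, config.horizon_year + 1)
    n_fc = config.horizon_year - config.year_end
    ages = sorted({a for (_, a, _) in dists})
    out = {}
    for (loc, age, sex), arr in dists.items():
        n_draws = arr.shape[0]
        full = np.empty((n_draws, len(years_all), N_BINS))
        full[:, : len(years_est)] = arr
        age_lo = int(age) - (config.age_group_width - 1) // 2
        start = max(fc_mod.roc_start_year(age_lo), config.year_end + 1)
        for d in range(n_draws):
            series = {int(y): arr[d, i] for i, y in enumerate(years_est)}
            roc = fc_mod.compute_roc(series)
            # cohort carry-over for years before the staged ROC start
            for year in range(config.year_end + 1, start):
                age_prime = age - (year - config.year_end)
                if age_prime < min(ages):
                    start = year  # no younger estimate to carry: start ROC here
                    break
                carried = np.empty(N_BINS)
                base = np.array([dists[(loc, a, sex)][d, -1] for a in ages])
                for b in range(N_BINS):
                    carried[b] = np.interp(age_prime, ages, base[:, b])
                carried = np.clip(carried, 0, None)
                full[d, len(years_est) + year - config.year_end - 1] = carried / carried.sum()
            anchor = full[d, len(years_est) + (start - config.year_end) - 2] \
                if start > config.year_end + 1 else arr[d, -1]
            proj = fc_mod.project(anchor, roc, config.horizon_year, start_year=start)
            for year, dist in proj.items():
                full[d, len(years_est) + year - config.year_end - 1] = dist
        out[(loc, age, sex)] = full
    return out


# ---------------------------------------------------------------------------
# stage 9: metrics


def _metrics_vectorized(dist_draws: np.ndarray) -> dict:
    """Metric draws for a (n_draws, 19) array."""
    m = dist_draws @ BIN_YEARS
    absdiff = np.abs(BIN_YEARS[:, None] - BIN_YEARS[None, :])
    aid = np.einsum("dj,jk,dk->d", dist_draws, absdiff, dist_draws)
    with np.errstate(divide="ignore", invalid="ignore"):
        gini = np.where(m > 0, aid / (2.0 * m), 0.0)
    out = {"mean_years": m, "aid": aid, "gini": gini}
    for t in metrics_mod.ATTAINMENT_THRESHOLDS:
        out[f"attainment_{t}plus"] = dist_draws[:, t:].sum(axis=1)
    return out


@_stage("metrics")
def compute_metrics(dists: dict, hierarchy: Hierarchy, config: RunConfig,
                    population: pd.DataFrame = None) -> pd.DataFrame:
    """Metric table with uncertainty intervals for countries and aggregates.

    ``population`` (entity=location_id, year, sex, population) weights the
    aggregation; equal weights by default.  Aggregates are built by
    averaging member distributions before computing metrics.
    """
    years_all = np.arange(config.year_start, config.horizon_year + 1)
    ages = sorted({a for (_, a, _) in dists})
    age_young = ages[0]

    def pop_weight(loc, year, sex):
        if population is None:
            return 1.0
        sel = population[(population["entity"] == loc) & (population["year"] == year)
                         & (population["sex"] == sex)]
        if len(sel) == 0:
            raise KeyError(f"missing population weight for {loc} {year} {sex}")
        return float(sel["population"].iloc[0])

    rows = []

    def emit(entity, sex, arr):
        # arr: (n_draws, n_years, 19)
        for i, year in enumerate(years_all):
            per = _metrics_vectorized(arr[:, i])
            for name, vals in per.items():
                rows.append({"entity": entity, "sex": sex, "year": int(year), "metric": name,
                             **metrics_mod.summarize_draws(vals)})
        return arr

    locs = sorted({l for (l, _, _) in dists})
    both_sex = {}
    for loc in locs:
        per_sex = {}
        for sex in syn_mod.SEXES:
            arr = dists[(loc, age_young, sex)]
            per_sex[sex] = arr
            emit(loc, sex, arr)
        w = np.array([[pop_weight(loc, y, s) for y in years_all] for s in syn_mod.SEXES])
        w = w / w.sum(axis=0, keepdims=True)
        both = (w[0, None, :, None] * per_sex["male"]
                + w[1, None, :, None] * per_sex["female"])
        both_sex[loc] = both
        emit(loc, "both", both)
        gap = per_sex["male"] @ BIN_YEARS - per_sex["female"] @ BIN_YEARS
        for i, year in enumerate(years_all):
            rows.append({"entity": loc, "sex": "both", "year": int(year),
                         "metric": "gender_gap_mean_years",
                         **metrics_mod.summarize_draws(gap[:, i])})
    for region in hierarchy.regions:
        members = [both_sex[l] for l in hierarchy.countries_in_region(region) if l in both_sex]
        if members:
            emit(region, "both", np.mean(members, axis=0))
    emit("global", "both", np.mean(list(both_sex.values()), axis=0))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run + validation


def run_pipeline(config: RunConfig, workdir=None) -> dict:
    """Execute all stages; return the estimate store.

    The store maps stage names to frames/arrays; when ``workdir`` is given,
    CSV artifacts with the seed and config hash are written there.
    """
    hierarchy, truth, obs_df, gold_map = simulate_scenario(config)
    store = estimate_summaries(obs_df, hierarchy, gold_map, config)
    store.update({"hierarchy": hierarchy, "truth": truth, "observations": obs_df,
                  "gold_map": gold_map, "config": config})
    dists = reconstruct_distributions(obs_df, store["draws"], hierarchy, config)
    store["distributions"] = dists
    store["forecast"] = forecast_distributions(dists, config)
    store["metrics"] = compute_metrics(store["forecast"], hierarchy, config)
    if workdir is not None:
        write_store(store, workdir)
    return store


def write_store(store: dict, workdir) -> None:
    import os

    os.makedirs(workdir, exist_ok=True)
    config: RunConfig = store["config"]
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}
    store["hierarchy"].to_csv(os.path.join(workdir, "hierarchy.csv"))
    for name in ("observations", "points", "adjusted", "extrapolated", "prior",
                 "posterior", "metrics"):
        df = store[name].copy()
        for k, v in stamp.items():
            df[k] = v
        df.to_csv(os.path.join(workdir, f"{name}.csv"), index=False)
    # distribution means (draw-averaged) in long format
    years_all = np.arange(config.year_start, config.horizon_year + 1)
    rows = []
    for (loc, age, sex), arr in store["forecast"].items():
        mean_dist = arr.mean(axis=0)
        for i, year in enumerate(years_all):
            rows.append({"location_id": loc, "age": age, "sex": sex, "year": int(year),
                         **{f"p{k}": mean_dist[i, k] for k in range(N_BINS)}, **stamp})
    pd.DataFrame(rows).to_csv(os.path.join(workdir, "distributions.csv"), index=False)
    config.to_file(os.path.join(workdir, "config.txt"))


@dataclass
class ErrorReport:
    """Out-of-sample predictions vs held-out observations."""

    per_point: pd.DataFrame

    def summaries(self, by=None) -> pd.DataFrame:
        df = self.per_point.copy()
        df["error"] = df["predicted"] - df["observed"]
        keys = ["quantity"] + (list(by) if by else [])
        out = df.groupby(keys).agg(
            rmse=("error", lambda e: float(np.sqrt(np.mean(e**2)))),
            mae=("error", lambda e: float(np.mean(np.abs(e)))),
            bias=("error", "mean"),
            n=("error", "size"),
        ).reset_index()
        return out

    def stratified(self) -> dict:
        strata = {}
        df = self.per_point
        if len(df) == 0:
            return {"overall": self.summaries()}
        strata["overall"] = self.summaries()
        strata["by_region"] = self.summaries(by=["region"])
        strata["by_period"] = self.summaries(by=["period"])
        strata["by_provider"] = self.summaries(by=["provider"])
        return strata


def holdout_validation(config: RunConfig, seed: int = None,
                       obs_df: pd.DataFrame = None, hierarchy: Hierarchy = None,
                       gold_map: adjust_mod.GoldMap = None) -> ErrorReport:
    """Block holdout: drop whole provider-location-year survey blocks, refit
    stages 2-6 on the rest, and score predictions of the held-out summaries.

    ``seed`` defaults to the config seed; a fraction of 0 blocks (possible at
    small scales) yields an empty report.
    """
    if obs_df is None:
        hierarchy, _, obs_df, gold_map = simulate_scenario(config)
    rng = np.random.default_rng(derive_seed(config.seed if seed is None else seed, "holdout"))
    blocks = obs_df[["provider", "location_id", "year"]].drop_duplicates().reset_index(drop=True)
    n_hold = int(round(config.holdout_fraction * len(blocks)))
    if n_hold == 0:
        return ErrorReport(per_point=pd.DataFrame(
            columns=["quantity", "location_id", "age", "sex", "year", "provider",
                     "region", "period", "observed", "predicted"]))
    held = blocks.iloc[rng.choice(len(blocks), size=n_hold, replace=False)]
    key_cols = ["provider", "location_id", "year"]
    merged = obs_df.merge(held.assign(_held=True), on=key_cols, how="left")
    train = merged[merged["_held"].isna()].drop(columns="_held")
    test = merged[merged["_held"].notna()].drop(columns="_held")

    store = estimate_summaries(train, hierarchy, gold_map, config)
    post = store["posterior"].set_index(
        ["location_id", "age", "sex", "quantity", "year"])["post_value"]

    # score against bias-adjusted held-out values (training fits), so the
    # error measures prediction quality rather than known provider bias
    test_points = adjust_points(adjust_mod.points_from_observations(test), hierarchy,
                                gold_map, fits=store["bias_fits"])
    rows = []
    for rec in test_points.to_dict("records"):
        key = (rec["location_id"], rec["age"], rec["sex"], rec["quantity"], int(rec["year"]))
        if key not in post.index:
            continue  # outside the estimation age grid
        rows.append({**{c: rec[c] for c in ("quantity", "location_id", "age", "sex",
                                            "year", "provider")},
                     "region": hierarchy.region_of(rec["location_id"]),
                     "period": "pre-2000" if rec["year"] < 2000 else "2000-2018",
                     "observed": rec["value"], "predicted": float(post.loc[key])})
    return ErrorReport(per_point=pd.DataFrame(rows))
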