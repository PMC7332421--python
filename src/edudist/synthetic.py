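"""Synthetic worlds with known truth for parameter-recovery testing.

A *truth surface* assigns every (country, sex, birth cohort) a 19-bin
distribution of completed years of schooling.  Cohort mean attainment follows
a logistic growth curve in cohort year; the distribution shape is a
two-component mixture (a spike at 0 years plus a discretized unimodal bulk
over 1-18), so the pair (mean, proportion-zero) does not determine the full
shape.  Cohort distributions are constant at ages >= 25 (educational
attainment is assumed stable after age 25); below 25 attainment is truncated
at what is attainable by that age.

Simulated surveys perturb the truth with provider-specific additive biases on
the logit scale of the two modelled summaries (mean/18 and proportion-zero),
applied through a calibrated exponential tilt, plus multinomial sampling
noise shrinking with effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from edudist._utils import N_BINS, check_distribution, dist_mean, expit, logit
from edudist.hierarchy import Hierarchy

SEXES = ("male", "female")

#: logit-scale grid points used for the bulk component over bins 1..18
_BULK_Z = np.log((np.arange(1, N_BINS) / N_BINS) / (1 - np.arange(1, N_BINS) / N_BINS))


# ---------------------------------------------------------------------------
# distribution construction


def _bulk_pmf(mu: float, s: float) -> np.ndarray:
    """Discretized logit-normal bulk over bins 1..18 (18 values, sum 1)."""
    logw = -0.5 * ((_BULK_Z - mu) / s) ** 2
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def _calibrate_bulk(target_mean: float, s: float, tol: float = 1e-10) -> np.ndarray:
    """Find the bulk pmf whose mean over bins 1..18 equals ``target_mean``.

    The location parameter is solved by bisection; the bulk mean is strictly
    increasing in it (monotone likelihood ratio in the bin index).
    """
    lo, hi = -40.0, 40.0
    target = float(np.clip(target_mean, 1.0 + 1e-9, 18.0 - 1e-9))
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        m = float(np.dot(_bulk_pmf(mid, s), np.arange(1, N_BINS)))
        if abs(m - target) < tol:
            break
        if m < target:
            lo = mid
        else:
            hi = mid
    return _bulk_pmf(0.5 * (lo + hi), s)


def mixture_distribution(mean: float, prop_zero: float, dispersion: float) -> np.ndarray:
    """19-bin distribution with the given mean and proportion-zero.

    Point mass ``prop_zero`` at bin 0 plus a discretized logit-normal bulk
    over bins 1..18 calibrated so the overall mean equals ``mean`` (where
    feasible; the bulk mean is clamped to (1, 18)).
    """
    if not (0.0 <= prop_zero < 1.0):
        raise ValueError("prop_zero must be in [0, 1)")
    bulk_target = mean / (1.0 - prop_zero)
    bulk = _calibrate_bulk(bulk_target, dispersion)
    out = np.empty(N_BINS)
    out[0] = prop_zero
    out[1:] = (1.0 - prop_zero) * bulk
    return out


def tilt_distribution(dist: np.ndarray, bias_mean18: float = 0.0, bias_p0: float = 0.0) -> np.ndarray:
    """Perturb a distribution so its two summaries shift by additive logit biases.

    The proportion-zero is moved directly on the logit scale; the bulk over
    bins 1..18 is exponentially tilted so the overall mean matches
    ``expit(logit(mean/18) + bias_mean18) * 18`` (clamped to the bulk's
    feasible range).  Zero biases return the input unchanged.
    """
    dist = np.asarray(dist, dtype=float)
    if bias_mean18 == 0.0 and bias_p0 == 0.0:
        return dist.copy()
    p0 = dist[0]
    bulk = dist[1:]
    if bulk.sum() <= 0:
        return dist.copy()  # degenerate all-zero-years: nothing to tilt
    bulk = bulk / bulk.sum()

    new_p0 = float(expit(logit(p0) + bias_p0)) if bias_p0 != 0.0 else p0
    mean = dist_mean(dist)
    new_mean = float(expit(logit(mean / 18.0) + bias_mean18)) * 18.0
    bulk_target = new_mean / (1.0 - new_p0)

    support = np.arange(1, N_BINS, dtype=float)
    lo_feasible = support[bulk > 0].min() + 1e-9
    hi_feasible = support[bulk > 0].max() - 1e-9
    bulk_target = float(np.clip(bulk_target, lo_feasible, hi_feasible))

    # exponential tilt: bulk_k * exp(theta * k), theta solved by bisection
    lo, hi = -10.0, 10.0
    for _ in range(200):
        theta = 0.5 * (lo + hi)
        w = bulk * np.exp(theta * support)
        w = w / w.sum()
        m = float(np.dot(w, support))
        if abs(m - bulk_target) < 1e-11:
            break
        if m < bulk_target:
            lo = theta
        else:
            hi = theta
    out = np.empty(N_BINS)
    out[0] = new_p0
    out[1:] = (1.0 - new_p0) * w
    return out


def _truncate_for_age(dist: np.ndarray, age: int) -> np.ndarray:
    """Move mass above the attainable-by-age cap onto the cap (school start at 6)."""
    cap = int(min(N_BINS - 1, max(0, age - 6)))
    if cap >= N_BINS - 1:
        return dist
    out = dist.copy()
    out[cap] += out[cap + 1 :].sum()
    out[cap + 1 :] = 0.0
    return out


# ---------------------------------------------------------------------------
# truth surface


@dataclass
class TruthSurface:
    """Per (country, sex): logistic-growth parameters defining cohort distributions.

    ``params`` maps (location_id, sex) to a dict with keys ``midpoint``
    (cohort year of half-growth), ``rate``, ``asymptote`` (limiting mean
    years), ``floor`` (early-cohort mean), ``dispersion`` (bulk spread),
    ``p0_coef`` and ``p0_gamma`` (link from mean to proportion-zero).
    """

    params: dict
    cohort_range: tuple
    _cache: dict = field(default_factory=dict, repr=False)

    def cohort_mean(self, location, sex, cohort: int) -> float:
        p = self.params[(location, sex)]
        g = expit(p["rate"] * (cohort - p["midpoint"]))
        return p["floor"] + (p["asymptote"] - p["floor"]) * float(g)

    def _prop_zero(self, mean: float, p) -> float:
        p0 = p["p0_coef"] * (1.0 - mean / 18.0) ** p["p0_gamma"]
        # keep the bulk-mean target inside its feasible range (1, 18)
        p0 = max(p0, 1.0 - mean / 1.05)
        p0 = min(p0, max(0.0, 1.0 - mean / 17.95))
        return float(np.clip(p0, 0.0, 0.97))

    def distribution(self, location, sex, cohort: int) -> np.ndarray:
        """The cohort's stable (age >= 25) 19-bin attainment distribution."""
        lo, hi = self.cohort_range
        if not (lo <= cohort <= hi):
            raise LookupError(f"cohort {cohort} outside range {self.cohort_range}")
        key = (location, sex, int(cohort))
        if key not in self._cache:
            p = self.params[(location, sex)]
            m = self.cohort_mean(location, sex, cohort)
            p0 = self._prop_zero(m, p)
            self._cache[key] = mixture_distribution(m, p0, p["dispersion"])
        return self._cache[key].copy()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        lo, hi = self.cohort_range
        for (location, sex) in sorted(self.params):
            for cohort in range(lo, hi + 1):
                d = self.distribution(location, sex, cohort)
                rows.append({"location_id": location, "sex": sex, "cohort": cohort,
                             **{f"p{k}": d[k] for k in range(N_BINS)}})
        return pd.DataFrame(rows)


def truth_summary(truth: TruthSurface, location, age: int, sex, year: int) -> np.ndarray:
    """Truth distribution for a (location, age, sex, year) query.

    Resolves the birth cohort as ``year - age``.  Queries at ages >= 25 for
    the same cohort return identical vectors regardless of year; below 25 the
    distribution is truncated at the attainable number of years.
    """
    cohort = int(year) - int(age)
    dist = truth.distribution(location, sex, cohort)
    if age < 25:
        dist = _truncate_for_age(dist, int(age))
    return dist


# ---------------------------------------------------------------------------
# world generation


def make_world(
    n_super: int,
    n_regions_per: int,
    n_countries_per: int,
    year_range: tuple,
    seed: int,
) -> tuple:
    """Generate a location hierarchy and a truth surface.

    Regions share growth-curve tendencies (regional mean parameters with
    country-level jitter) so regional pooling in downstream models is
    meaningful.  Deterministic for a fixed seed.
    """
    if min(n_super, n_regions_per, n_countries_per) < 1:
        raise ValueError("all hierarchy counts must be >= 1")
    y0, y1 = int(year_range[0]), int(year_range[1])
    if y1 < y0:
        raise ValueError("year_range must be increasing")
    cohort_range = (y0 - 95, y1 - 15)
    if cohort_range[1] - cohort_range[0] + 1 < 30:
        raise ValueError("year_range must cover at least 30 cohorts")

    rng = np.random.default_rng(seed)
    rows = []
    params = {}
    for i in range(1, n_super + 1):
        sr = f"SR{i}"
        for j in range(1, n_regions_per + 1):
            region = f"{sr}_R{j}"
            reg_mid = rng.uniform(1930.0, 1985.0)
            reg_asym = rng.uniform(12.0, 17.5)
            reg_rate = rng.uniform(0.04, 0.09)
            for k in range(1, n_countries_per + 1):
                loc = f"{region}_C{k}"
                rows.append({"location_id": loc, "region": region, "super_region": sr})
                base_mid = reg_mid + rng.uniform(-8.0, 8.0)
                base_asym = float(np.clip(reg_asym + rng.uniform(-1.5, 1.5), 8.0, 18.0))
                base_rate = float(np.clip(reg_rate + rng.uniform(-0.015, 0.015), 0.02, 0.12))
                female_lag = rng.uniform(0.0, 10.0)
                for sex in SEXES:
                    params[(loc, sex)] = {
                        "midpoint": base_mid + (female_lag if sex == "female" else 0.0),
                        "rate": base_rate,
                        "asymptote": base_asym - (rng.uniform(0.0, 1.0) if sex == "female" else 0.0),
                        "floor": rng.uniform(0.4, 1.5),
                        "dispersion": rng.uniform(0.7, 1.4),
                        "p0_coef": rng.uniform(0.35, 0.85),
                        "p0_gamma": rng.uniform(1.5, 2.5),
                    }
    hierarchy = Hierarchy(pd.DataFrame(rows))
    truth = TruthSurface(params=params, cohort_range=cohort_range)
    return hierarchy, truth


# ---------------------------------------------------------------------------
# providers and observations


@dataclass(frozen=True)
class ProviderSpec:
    """A simulated data provider.

    ``age_group_width`` is 1 (single ages) or 5 (5-year groups reported with
    their bounds; the pipeline consumes midpoints).  ``n_eff`` is the
    effective sample size per reported cell; ``no_noise`` disables sampling
    noise entirely (infinite sample size).
    """

    name: str
    bias_mean18: float = 0.0
    bias_p0: float = 0.0
    gold: bool = False
    years: Sequence[int] = ()
    age_group_width: int = 1
    locations: Sequence = ()
    n_eff: float = 1000.0
    no_noise: bool = False

    def __post_init__(self):
        if self.age_group_width not in (1, 5):
            raise ValueError("age_group_width must be 1 or 5")
        if not self.no_noise and self.n_eff <= 0:
            raise ValueError("n_eff must be positive")


@dataclass
class Observation:
    """One survey tabulation cell."""

    location_id: str
    provider: str
    year: int
    sex: str
    age_lo: int
    age_hi: int
    n_eff: float
    props: np.ndarray

    def __post_init__(self):
        self.props = check_distribution(self.props)
        if self.age_lo < 15:
            raise ValueError("age must be >= 15")

    @property
    def age_mid(self) -> float:
        return 0.5 * (self.age_lo + self.age_hi)


def simulate_survey(
    truth: TruthSurface,
    provider_spec: ProviderSpec,
    seed: int,
    ages: Sequence[int] = tuple(range(25, 40)),
    sexes: Sequence[str] = SEXES,
) -> list:
    """Simulate all observations contributed by one provider.

    For each (location, year, sex): single-age truth distributions are
    biased via :func:`tilt_distribution`, optionally degraded with
    multinomial noise at ``n_eff``, and reported either as single ages or as
    5-year groups (sample-size-weighted averages of the member ages).
    """
    spec = provider_spec
    lo, hi = truth.cohort_range
    for y in spec.years:
        if not (lo <= int(y) - max(ages) and int(y) - min(ages) <= hi):
            raise ValueError(f"survey year {y} not coverable by truth cohort range")
    rng = np.random.default_rng(seed)
    out = []
    for loc in spec.locations:
        for year in spec.years:
            for sex in sexes:
                cells = {}
                for age in ages:
                    d = truth_summary(truth, loc, age, sex, year)
                    d = tilt_distribution(d, spec.bias_mean18, spec.bias_p0)
                    if not spec.no_noise:
                        counts = rng.multinomial(int(round(spec.n_eff)), d)
                        d = counts / counts.sum()
                    cells[age] = d
                if spec.age_group_width == 1:
                    for age, d in cells.items():
                        out.append(Observation(loc, spec.name, int(year), sex,
                                               int(age), int(age),
                                               np.inf if spec.no_noise else spec.n_eff, d))
                else:
                    for g0 in range(min(ages), max(ages) + 1, 5):
                        member = [a for a in cells if g0 <= a < g0 + 5]
                        if not member:
                            continue
                        avg = np.mean([cells[a] for a in member], axis=0)
                        n_tot = np.inf if spec.no_noise else spec.n_eff * len(member)
                        out.append(Observation(loc, spec.name, int(year), sex,
                                               int(min(member)), int(max(member)), n_tot, avg))
    return out


# ---------------------------------------------------------------------------
# CSV interfaces

OBS_COLUMNS = ["location_id", "provider", "year", "sex", "age_lo", "age_hi", "n_eff"] + [
    f"p{k}" for k in range(N_BINS)
]


def observations_to_frame(observations: Sequence[Observation]) -> pd.DataFrame:
    rows = []
    for o in observations:
        rows.append({"location_id": o.location_id, "provider": o.provider, "year": o.year,
                     "sex": o.sex, "age_lo": o.age_lo, "age_hi": o.age_hi, "n_eff": o.n_eff,
                     **{f"p{k}": o.props[k] for k in range(N_BINS)}})
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def frame_to_observations(df: pd.DataFrame) -> list:
    pcols = [f"p{k}" for k in range(N_BINS)]
    return [
        Observation(r.location_id, r.provider, int(r.year), r.sex, int(r.age_lo),
                    int(r.age_hi), float(r.n_eff), np.array([getattr(r, c) for c in pcols]))
        for r in df.itertuples(index=False)
    ]


def write_observations_csv(observations, path) -> None:
    observations_to_frame(observations).to_csv(path, index=False)


def read_observations_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
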