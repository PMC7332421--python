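"""K-nearest-neighbour reconstruction of full attainment distributions.

Each target location-age-sex-year cell carries a 2-vector of modelled
summaries (logit(mean/18), logit(prop-zero)).  Candidates from the library
of observed distributions are selected by Mahalanobis distance on that
feature space, combined with weights driven by age, birth-cohort and spatial
closeness, averaged bin-wise, and Loess-smoothed over time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from statsmodels.nonparametric.smoothers_lowess import lowess

from edudist._utils import BIN_YEARS, N_BINS, dist_mean, logit
from edudist.hierarchy import Hierarchy

logger = logging.getLogger(__name__)

#: floor of the min-max rescaled distances (and the same-country spatial tier)
DIST_FLOOR = 0.001


@dataclass(frozen=True)
class EnsembleConfig:
    k: int = 80
    p_age: float = 0.25
    p_cohort: float = 0.85
    p_space: float = 0.7
    psi: float = 2.5
    loess_span: float = 0.5

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.psi <= 0:
            raise ValueError("psi must be positive")
        if not (0 < self.loess_span <= 1):
            raise ValueError("loess_span must be in (0, 1]")
        for name in ("p_age", "p_cohort", "p_space"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class CandidateLibrary:
    """Searchable pool of observed single-year distributions.

    ``features`` is (n, 2): (logit(mean/18), logit(prop_zero)) per entry;
    ``cov`` is the pooled 2x2 feature covariance used for Mahalanobis
    distances, computed once from the full library.
    """

    features: np.ndarray
    bins: np.ndarray
    meta: pd.DataFrame  # columns: location_id, age, cohort, provider
    cov: np.ndarray = field(default=None)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.bins = np.asarray(self.bins, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != 2:
            raise ValueError("features must be (n, 2)")
        if self.bins.shape != (len(self.features), N_BINS):
            raise ValueError("bins shape mismatch")
        if np.abs(self.bins.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("library entries must sum to 1")
        if self.cov is None:
            self.cov = np.cov(self.features, rowvar=False)

    def __len__(self) -> int:
        return len(self.features)

    def cov_factor(self):
        """Cached Cholesky factor of the feature covariance."""
        if not hasattr(self, "_cov_factor"):
            try:
                self._cov_factor = cho_factor(self.cov)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    "feature covariance is singular; check the library features for degeneracy"
                ) from None
        return self._cov_factor

    def location_distances(self, target_location, hierarchy: Hierarchy) -> np.ndarray:
        """Cached tiered spatial distance of every entry to a target country."""
        if not hasattr(self, "_loc_dist_cache"):
            self._loc_dist_cache = {}
        if target_location not in self._loc_dist_cache:
            tiers = {loc: hierarchy.location_distance(target_location, loc)
                     for loc in self.meta["location_id"].unique()}
            self._loc_dist_cache[target_location] = (
                self.meta["location_id"].map(tiers).to_numpy(dtype=float))
        return self._loc_dist_cache[target_location]


def build_library(obs_df: pd.DataFrame, hierarchy: Hierarchy = None) -> CandidateLibrary:
    """Build the candidate library from an observation table.

    One entry per observation row; features are the logit-scale summaries of
    the observed 19-bin vector.  The birth cohort is survey year minus
    midpoint age.
    """
    pcols = [f"p{k}" for k in range(N_BINS)]
    bins = obs_df[pcols].to_numpy(dtype=float)
    bins = bins / bins.sum(axis=1, keepdims=True)
    means = bins @ BIN_YEARS
    features = np.column_stack([logit(means / 18.0), logit(bins[:, 0])])
    age_mid = 0.5 * (obs_df["age_lo"].to_numpy() + obs_df["age_hi"].to_numpy())
    meta = pd.DataFrame({
        "location_id": obs_df["location_id"].to_numpy(),
        "age": age_mid,
        "cohort": obs_df["year"].to_numpy() - age_mid,
        "provider": obs_df["provider"].to_numpy(),
    })
    return CandidateLibrary(features=features, bins=bins, meta=meta)


def mahalanobis_select(query, library: CandidateLibrary, k: int):
    """Indices and distances of the K library entries closest to ``query``.

    Distance is sqrt((H_i - q)^T S^-1 (H_i - q)) with S the library's pooled
    feature covariance.  Ties are broken by library index order.
    """
    query = np.asarray(query, dtype=float)
    if len(library) < k:
        raise ValueError(f"library has {len(library)} < k={k} entries")
    factor = library.cov_factor()
    diff = library.features - query
    d2 = np.einsum("ij,ij->i", diff, cho_solve(factor, diff.T).T)
    d = np.sqrt(np.clip(d2, 0.0, None))
    order = np.lexsort((np.arange(len(d)), d))[:k]
    return order, d[order]


def _rescale(raw: np.ndarray) -> np.ndarray:
    """Min-max rescale to [DIST_FLOOR, 1] across the candidate set."""
    raw = np.asarray(raw, dtype=float)
    span = raw.max() - raw.min()
    if span == 0.0:
        return np.full_like(raw, DIST_FLOOR)
    return DIST_FLOOR + (1.0 - DIST_FLOOR) * (raw - raw.min()) / span


def ensemble_weights(
    target_age: float,
    target_cohort: float,
    target_location,
    candidates: pd.DataFrame,
    hierarchy: Hierarchy,
    config: EnsembleConfig = EnsembleConfig(),
) -> np.ndarray:
    """Normalized candidate weights from age, cohort and spatial closeness.

    Distance_i = (P_age * D_age)^psi + (P_cohort * D_cohort)^psi
               + (P_space * D_loc)^psi, with age and cohort distances
    min-max rescaled to [0.001, 1] across the candidate set and the spatial
    distance given by hierarchy tiers; weights are 1/Distance_i, normalized.
    """
    d_age = _rescale(np.abs(candidates["age"].to_numpy(dtype=float) - target_age))
    d_cohort = _rescale(np.abs(candidates["cohort"].to_numpy(dtype=float) - target_cohort))
    d_loc = np.array([hierarchy.location_distance(target_location, c)
                      for c in candidates["location_id"]])
    dist = ((config.p_age * d_age) ** config.psi
            + (config.p_cohort * d_cohort) ** config.psi
            + (config.p_space * d_loc) ** config.psi)
    w = 1.0 / dist
    return w / w.sum()


def ensemble_average(candidate_bins, weights) -> np.ndarray:
    """Bin-wise weighted average of candidate distributions."""
    candidate_bins = np.asarray(candidate_bins, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be normalized")
    return weights @ candidate_bins


_SMOOTHER_CACHE: dict = {}


def _loess_matrix(years: np.ndarray, span: float) -> np.ndarray:
    """Linear-smoother matrix of degree-1 Loess (tricube weights, no
    robustness iterations) on a fixed year grid.

    Built by smoothing unit vectors, so applying it to any series is exactly
    equivalent to calling the smoother on that series.
    """
    key = (tuple(years), span)
    if key not in _SMOOTHER_CACHE:
        n = len(years)
        cols = [lowess(np.eye(n)[:, j], years, frac=span, it=0, return_sorted=False)
                for j in range(n)]
        _SMOOTHER_CACHE[key] = np.column_stack(cols)
    return _SMOOTHER_CACHE[key]


def loess_smooth_bins(years, series, span: float = 0.5) -> np.ndarray:
    """Per-bin Loess smoothing over time, clipped and renormalized yearly.

    ``series`` is (n_years, 19).  Series shorter than 5 years pass through
    with a warning.
    """
    years = np.asarray(years, dtype=float)
    series = np.asarray(series, dtype=float)
    if len(years) < 5:
        warnings.warn("series shorter than 5 years: Loess smoothing skipped")
        return series.copy()
    out = _loess_matrix(years, span) @ series
    out = np.clip(out, 0.0, None)
    return out / out.sum(axis=1, keepdims=True)


def reconstruct_series(
    query_features,
    years,
    target_age: float,
    target_location,
    library: CandidateLibrary,
    hierarchy: Hierarchy,
    config: EnsembleConfig = EnsembleConfig(),
    smooth: bool = True,
) -> np.ndarray:
    """Reconstruct a year-indexed distribution series for one target cell.

    ``query_features`` is (n_years, 2) on the logit feature scale (one GPR
    draw).  Returns (n_years, 19).
    """
    query_features = np.asarray(query_features, dtype=float)
    years = np.asarray(years)
    factor = library.cov_factor()
    lib_age = library.meta["age"].to_numpy(dtype=float)
    lib_cohort = library.meta["cohort"].to_numpy(dtype=float)
    d_loc_all = library.location_distances(target_location, hierarchy)

    # batched Mahalanobis distances: (n_years, n_lib)
    diff = library.features[None, :, :] - query_features[:, None, :]
    sinv_diff = cho_solve(factor, diff.reshape(-1, 2).T).T.reshape(diff.shape)
    d2 = np.einsum("tij,tij->ti", diff, sinv_diff)

    out = np.empty((len(years), N_BINS))
    for t, year in enumerate(years):
        part = np.argpartition(d2[t], config.k - 1)[: config.k]
        idx = part[np.lexsort((part, d2[t][part]))]
        d_age = _rescale(np.abs(lib_age[idx] - target_age))
        d_cohort = _rescale(np.abs(lib_cohort[idx] - (float(year) - target_age)))
        dist = ((config.p_age * d_age) ** config.psi
                + (config.p_cohort * d_cohort) ** config.psi
                + (config.p_space * d_loc_all[idx]) ** config.psi)
        w = 1.0 / dist
        out[t] = (w / w.sum()) @ library.bins[idx]
    if smooth:
        out = loess_smooth_bins(years, out, config.loess_span)
    return out
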