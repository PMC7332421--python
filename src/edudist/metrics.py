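"""SDG-progress and inequality metrics on 19-bin attainment distributions.

All metrics operate on normalized 19-bin vectors (years 0..18).  The average
interpersonal difference (AID) is the mean absolute difference in years of
schooling over all ordered pairs of individuals (self-pairs included), which
makes the identity AID = 2 * mean * Gini exact with the with-replacement
population Gini.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from edudist._utils import BIN_YEARS, N_BINS, check_distribution, dist_mean

logger = logging.getLogger(__name__)

ATTAINMENT_THRESHOLDS = (6, 12, 15)  # primary, secondary, tertiary completion

#: |j - k| over all bin pairs, precomputed
_ABS_DIFF = np.abs(BIN_YEARS[:, None] - BIN_YEARS[None, :])


def attainment_proportion(dist, threshold: int) -> float:
    """Proportion with at least ``threshold`` completed years of schooling."""
    dist = check_distribution(dist)
    return float(dist[threshold:].sum())


def aid(dist) -> float:
    """Average interpersonal difference in years of schooling.

    ``sum_j sum_k p_j p_k |j - k|`` over all ordered pairs, self-pairs
    included.
    """
    dist = check_distribution(dist)
    return float(dist @ _ABS_DIFF @ dist)


def gini(dist) -> float:
    """Population Gini coefficient; 0 by convention when the mean is 0."""
    dist = check_distribution(dist)
    m = dist_mean(dist)
    if m == 0.0:
        logger.info("gini: zero-mean distribution, returning 0 by convention")
        return 0.0
    return aid(dist) / (2.0 * m)


def gender_gap_decomposition(dist_m, dist_f) -> dict:
    """Male-minus-female gap in mean years, split by schooling level.

    The contributions use expected years completed within each band
    (primary: years 1-6, secondary: 7-12, tertiary: 13-18, via caps at
    6/12/18); they sum to the total gap exactly.
    """
    dist_m = check_distribution(dist_m)
    dist_f = check_distribution(dist_f)

    def band(dist, lo, width):
        return float(np.dot(dist, np.clip(BIN_YEARS - lo, 0.0, width)))

    total = dist_mean(dist_m) - dist_mean(dist_f)
    primary = band(dist_m, 0, 6) - band(dist_f, 0, 6)
    secondary = band(dist_m, 6, 6) - band(dist_f, 6, 6)
    tertiary = band(dist_m, 12, 6) - band(dist_f, 12, 6)
    return {"total": total, "primary": primary, "secondary": secondary, "tertiary": tertiary}


def aggregate(dists, weights) -> np.ndarray:
    """Population-weighted aggregate distribution.

    Aggregation happens before metric computation, so inequality metrics on
    the aggregate include between-member spread.
    """
    dists = np.asarray(dists, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if dists.ndim != 2 or dists.shape[1] != N_BINS:
        raise ValueError(f"dists must be (n, {N_BINS})")
    if weights.shape != (dists.shape[0],):
        raise ValueError("one weight per distribution required")
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    return (weights / total) @ dists


def metric_set(dist) -> dict:
    """All scalar metrics for one distribution."""
    dist = check_distribution(dist)
    out = {f"attainment_{t}plus": attainment_proportion(dist, t) for t in ATTAINMENT_THRESHOLDS}
    out["mean_years"] = dist_mean(dist)
    out["aid"] = aid(dist)
    out["gini"] = gini(dist)
    return out


def summarize_draws(values, lower_q: float = 2.5, upper_q: float = 97.5) -> dict:
    """Mean and percentile uncertainty interval over metric draws."""
    values = np.asarray(values, dtype=float)
    return {
        "mean": float(values.mean()),
        "lower": float(np.percentile(values, lower_q)),
        "upper": float(np.percentile(values, upper_q)),
    }


def metrics_frame(dist_draws: dict) -> pd.DataFrame:
    """Long-format metrics table from a map of (entity, sex, year) -> draws array.

    ``dist_draws`` values are (n_draws, 19) arrays; the output has one row
    per (entity, sex, year, metric) with mean/lower/upper columns.
    """
    rows = []
    for (entity, sex, year), draws in dist_draws.items():
        draws = np.atleast_2d(np.asarray(draws, dtype=float))
        per_metric: dict = {}
        for d in draws:
            for name, value in metric_set(d).items():
                per_metric.setdefault(name, []).append(value)
        for name, vals in per_metric.items():
            rows.append({"entity": entity, "sex": sex, "year": year, "metric": name,
                         **summarize_draws(vals)})
    return pd.DataFrame(rows)
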