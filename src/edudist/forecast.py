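"""Rate-of-change forecasting of attainment distributions to 2030.

Each bin's proportion is projected on the logit scale using the average
annual logit rate of change (ROC) over the last 15 observed years
(2004-2018 differences); after each one-year step the back-transformed bins
are renormalized to the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from edudist._utils import N_BINS, check_distribution, dist_mean, expit

ROC_WINDOW_START = 2003
ROC_WINDOW_END = 2018
FORECAST_HORIZON = 2030

#: zero-proportion bins are clipped here before the logit, so empty bins can
#: only grow through renormalization
FORECAST_CLIP = 1e-6

#: forecast application start year by age-group lower bound: younger groups
#: leave cohort-model support first
ROC_START_YEAR = {25: 2019, 30: 2024, 35: 2029}


def _logit(p):
    p = np.clip(np.asarray(p, dtype=float), FORECAST_CLIP, 1.0 - FORECAST_CLIP)
    return np.log(p / (1.0 - p))


def roc_start_year(age_lo: int) -> int:
    """First year the ROC model applies for an age group (by lower bound)."""
    for lo in sorted(ROC_START_YEAR, reverse=True):
        if age_lo >= lo:
            return ROC_START_YEAR[lo]
    return ROC_START_YEAR[25]


@dataclass
class ForecastFit:
    """Per-bin annual logit rates of change anchored at a reference year."""

    roc: np.ndarray  # (19,)
    reference_year: int = ROC_WINDOW_END
    start_year: int = 2019

    def __post_init__(self):
        self.roc = np.asarray(self.roc, dtype=float)
        if self.roc.shape != (N_BINS,):
            raise ValueError(f"roc must have {N_BINS} entries")
        if not np.isfinite(self.roc).all():
            raise ValueError("roc values must be finite")


def compute_roc(series: dict) -> np.ndarray:
    """Average annual logit rate of change per bin over 2004-2018.

    Parameters
    ----------
    series : mapping year -> 19-bin distribution, covering 2003..2018.

    Returns
    -------
    (19,) array: the mean of the 15 annual logit differences per bin (which
    telescopes to ``[logit(p_2018) - logit(p_2003)] / 15``).
    """
    years = list(range(ROC_WINDOW_START, ROC_WINDOW_END + 1))
    missing = [y for y in years if y not in series]
    if missing:
        raise ValueError(f"series missing years required for ROC: {missing}")
    mat = np.vstack([_logit(np.asarray(series[y], dtype=float)) for y in years])
    return (mat[1:] - mat[:-1]).sum(axis=0) / 15.0


def project(series_2018, roc, horizon_year: int = FORECAST_HORIZON, start_year: int = 2019) -> dict:
    """Project a distribution forward one logit step per year, renormalizing.

    Returns a mapping year -> 19-bin distribution for
    ``start_year..horizon_year``.  A k-year projection is exactly k chained
    one-year projections.
    """
    if horizon_year > FORECAST_HORIZON:
        raise ValueError(f"horizon_year must be <= {FORECAST_HORIZON}")
    dist = check_distribution(series_2018, atol=1e-6)
    roc = np.asarray(roc, dtype=float)
    out = {}
    for year in range(start_year, horizon_year + 1):
        p = expit(_logit(dist) + roc)
        dist = p / p.sum()
        out[year] = dist
    return out


def mean_from_distribution(dist) -> float:
    """Mean years of schooling of a normalized distribution."""
    return dist_mean(check_distribution(dist, atol=1e-6))
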