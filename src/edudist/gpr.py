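"""Gaussian process smoothing of age-period residuals over calendar time.

Residuals of the logit-scale prior surface are smoothed per
location-age-sex series with an exact GP using a Matérn covariance
(smoothness 2, length-scale 40 years by default).  The kernel amplitude is
estimated per super-region and sex as the squared scaled median absolute
deviation of the prior residuals; per-point noise is the squared standard
error of each data point (plus any extrapolation prediction error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import gamma as gamma_fn
from scipy.special import kv
from scipy.stats import median_abs_deviation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GPRConfig:
    """Kernel and sampling settings."""

    nu: float = 2.0
    length_scale: float = 40.0
    amplitude: float = 1.0
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.nu <= 0 or self.length_scale <= 0:
            raise ValueError("nu and length_scale must be positive")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


def matern_cov(d, sigma2: float, nu: float = 2.0, length_scale: float = 40.0):
    """Matérn covariance at distance ``d``.

    sigma2 * 2^(1-nu)/Gamma(nu) * (d*sqrt(2 nu)/l)^nu * K_nu(d*sqrt(2 nu)/l),
    with the limit sigma2 at d = 0.
    """
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    scaled = d * np.sqrt(2.0 * nu) / length_scale
    with np.errstate(invalid="ignore"):
        out = sigma2 * (2.0 ** (1.0 - nu) / gamma_fn(nu)) * scaled**nu * kv(nu, scaled)
    out = np.where(d == 0.0, sigma2, out)
    if out.ndim == 0:
        return float(out)
    return out


def estimate_amplitude(residuals: pd.DataFrame, min_group: int = 10) -> dict:
    """Kernel amplitude sigma^2 per (super_region, sex) residual pool.

    sigma^2 is the squared median absolute deviation (scaled for normal
    consistency) of the logit-scale residuals from the prior mean.  Groups
    with fewer than ``min_group`` residuals fall back to the global pool.
    """
    if not {"super_region", "sex", "resid"}.issubset(residuals.columns):
        raise ValueError("residuals needs columns super_region, sex, resid")
    global_sigma2 = float(median_abs_deviation(residuals["resid"], scale="normal") ** 2)
    out = {}
    for (sr, sex), grp in residuals.groupby(["super_region", "sex"]):
        if len(grp) < min_group:
            logger.warning("amplitude group (%s, %s) has %d < %d residuals; using global pool",
                           sr, sex, len(grp), min_group)
            out[(sr, sex)] = global_sigma2
        else:
            out[(sr, sex)] = float(median_abs_deviation(grp["resid"], scale="normal") ** 2)
    return out


@dataclass
class PosteriorSeries:
    """GP posterior for one location-age-sex-quantity series (logit scale)."""

    years: np.ndarray
    prior_mean: np.ndarray
    posterior_mean: np.ndarray
    posterior_sd: np.ndarray
    draws: np.ndarray = field(repr=False)  # (n_draws, n_years)

    def __post_init__(self):
        n = len(self.years)
        for name in ("prior_mean", "posterior_mean", "posterior_sd"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if (self.posterior_sd < 0).any():
            raise ValueError("posterior_sd must be non-negative")


def gpr_posterior(
    years,
    prior_mean,
    data_years,
    data_values,
    data_noise_var,
    config: GPRConfig,
) -> PosteriorSeries:
    """Exact GP regression of logit-scale residuals over time.

    Posterior mean = prior + K_*^T (K + diag(noise))^-1 (data - prior at
    data years).  Draws are sampled antithetically from the posterior.  With
    zero data points the prior is returned with prior covariance.
    """
    years = np.asarray(years, dtype=float)
    prior_mean = np.asarray(prior_mean, dtype=float)
    data_years = np.asarray(data_years, dtype=float)
    data_values = np.asarray(data_values, dtype=float)
    data_noise_var = np.asarray(data_noise_var, dtype=float)
    s2, nu, ell = config.amplitude, config.nu, config.length_scale

    dist_grid = np.abs(years[:, None] - years[None, :])
    k_grid = matern_cov(dist_grid, s2, nu, ell)

    if len(data_years) == 0:
        post_mean = prior_mean.copy()
        post_cov = k_grid
    else:
        prior_at_data = np.interp(data_years, years, prior_mean)
        resid = data_values - prior_at_data
        k_dd = matern_cov(np.abs(data_years[:, None] - data_years[None, :]), s2, nu, ell)
        k_gd = matern_cov(np.abs(years[:, None] - data_years[None, :]), s2, nu, ell)
        noisy = k_dd + np.diag(data_noise_var)
        try:
            factor = cho_factor(noisy)
        except np.linalg.LinAlgError:
            factor = cho_factor(noisy + 1e-9 * np.eye(len(data_years)))
        alpha = cho_solve(factor, resid)
        post_mean = prior_mean + k_gd @ alpha
        post_cov = k_grid - k_gd @ cho_solve(factor, k_gd.T)

    post_sd = np.sqrt(np.clip(np.diag(post_cov), 0.0, None))

    rng = np.random.default_rng(config.seed)
    n_half = (config.n_draws + 1) // 2
    try:
        chol = cholesky(post_cov + 1e-10 * np.eye(len(years)), lower=True)
    except np.linalg.LinAlgError:
        # covariance numerically rank-deficient: eigen-decompose instead
        w, v = np.linalg.eigh(post_cov)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n_half, len(years)))
    half = z @ chol.T
    draws = post_mean + np.vstack([half, -half])[: config.n_draws]

    return PosteriorSeries(years=years, prior_mean=prior_mean, posterior_mean=post_mean,
                           posterior_sd=post_sd, draws=draws)
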