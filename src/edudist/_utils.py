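"""Shared numerical helpers: logit transforms with clipping, spline bases, checks."""

from __future__ import annotations

import numpy as np

N_BINS = 19  # years of schooling 0..18, top-coded at 18
BIN_YEARS = np.arange(N_BINS, dtype=float)

#: default clip applied to proportions before the logit transform
LOGIT_CLIP = 1e-4


def logit(p, clip: float = LOGIT_CLIP):
    """Logit with symmetric clipping to [clip, 1-clip]."""
    p = np.clip(np.asarray(p, dtype=float), clip, 1.0 - clip)
    return np.log(p / (1.0 - p))


def expit(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def dist_mean(dist) -> float:
    """Mean years of schooling of a 19-bin distribution."""
    return float(np.dot(np.asarray(dist, dtype=float), BIN_YEARS))


def check_distribution(dist, atol: float = 1e-8) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (N_BINS,):
        raise ValueError(f"distribution must have {N_BINS} bins, got shape {dist.shape}")
    if (dist < -atol).any():
        raise ValueError("distribution has negative bins")
    if abs(dist.sum() - 1.0) > atol:
        raise ValueError(f"distribution sums to {dist.sum():.6g}, not 1")
    return dist


def natural_spline_basis(x, knots, boundary) -> np.ndarray:
    """Natural cubic spline basis (without intercept column).

    Standard construction: truncated-cubic basis made linear beyond the
    boundary knots.  With ``k`` interior knots the basis has ``k + 1`` columns:
    the linear term plus ``k`` curvature terms.

    Parameters
    ----------
    x : array-like
        Evaluation points.
    knots : sequence of float
        Interior knots.
    boundary : (float, float)
        Boundary knots (spline is linear outside this range).
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(boundary[0]), float(boundary[1])
    if hi <= lo:
        raise ValueError("boundary knots must satisfy lo < hi")
    all_knots = np.sort(np.asarray(list(knots) + [lo, hi], dtype=float))

    def d(k, xv):
        # (x - k)^3_+ terms combined to enforce linearity beyond boundaries
        num = np.maximum(xv - k, 0.0) ** 3 - np.maximum(xv - all_knots[-1], 0.0) ** 3
        return num / (all_knots[-1] - k)

    cols = [x]
    for k in all_knots[:-2]:
        cols.append(d(k, x) - d(all_knots[-2], x))
    return np.column_stack(cols)


def derive_seed(seed: int, *labels) -> int:
    """Deterministically derive a child seed from a master seed and labels.

    Stable across processes (does not rely on Python's randomized ``hash``).
    """
    import zlib

    key = tuple(zlib.crc32(str(l).encode()) for l in labels)
    ss = np.random.SeedSequence(seed, spawn_key=key)
    return int(ss.generate_state(1)[0])
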