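"""Sampling and diagnostic primitives: vectorized slice sampling,
split-chain potential scale reduction, and WAIC.

The slice sampler updates a vector of coordinates whose full conditionals
are mutually independent given the rest of the model, which is what the
Gibbs scans of the hierarchical observer models need (all participant x
condition cells can be updated in one vectorized pass).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import logsumexp

log = logging.getLogger(__name__)


def slice_sample_vec(logpdf, x0: np.ndarray, width, rng: np.random.Generator,
                     max_stepout: int = 20, max_shrink: int = 100) -> np.ndarray:
    """One univariate slice-sampling update applied elementwise.

    ``logpdf(x)`` must return the per-coordinate conditional log density
    for a vector ``x`` of the same shape as ``x0`` (coordinates
    conditionally independent).  Uses the stepping-out procedure followed
    by shrinkage; coordinates that fail to find an acceptable point within
    ``max_shrink`` proposals keep their current value.
    """
    x0 = np.asarray(x0, dtype=float)
    width = np.broadcast_to(np.asarray(width, dtype=float), x0.shape).copy()
    logy = logpdf(x0) + np.log(rng.uniform(size=x0.shape))
    u = rng.uniform(size=x0.shape)
    lo = x0 - width * u
    hi = lo + width
    for _ in range(max_stepout):
        grow = logpdf(lo) > logy
        if not grow.any():
            break
        lo = np.where(grow, lo - width, lo)
    for _ in range(max_stepout):
        grow = logpdf(hi) > logy
        if not grow.any():
            break
        hi = np.where(grow, hi + width, hi)

    out = x0.copy()
    done = np.zeros(x0.shape, dtype=bool)
    for _ in range(max_shrink):
        prop = rng.uniform(lo, hi)
        accept = (logpdf(prop) > logy) & ~done
        out = np.where(accept, prop, out)
        done |= accept
        if done.all():
            break
        shrink_lo = ~done & (prop < x0)
        lo = np.where(shrink_lo, prop, lo)
        hi = np.where(~done & ~shrink_lo, prop, hi)
    return out


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``draws`` has shape (chains, samples).  Each chain is split in half;
    R-hat compares between- and within-half-chain variance.  Degenerate
    zero-variance input returns 1.0 with a warning.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 4:
        raise ValueError("need at least 2 chains of at least 4 draws")
    half = draws.shape[1] // 2
    split = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    n = split.shape[1]
    chain_means = split.mean(axis=1)
    w = split.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w == 0.0:
        log.warning("zero within-chain variance; R-hat defined as 1.0")
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def waic(loglik: np.ndarray) -> dict:
    """WAIC from a pointwise log-likelihood matrix (draws x points).

    lppd uses log-sum-exp stabilization; the penalty is the per-point
    posterior variance of the log-likelihood.  Returns the deviance-scale
    WAIC, the effective parameter count p_waic and pointwise -2*(lppd_i -
    p_i) contributions.
    """
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2 or loglik.size == 0:
        raise ValueError("loglik must be a non-empty (draws, points) matrix")
    if not np.all(np.isfinite(loglik)):
        raise ValueError("loglik contains non-finite values")
    s = loglik.shape[0]
    lppd_i = logsumexp(loglik, axis=0) - np.log(s)
    p_i = loglik.var(axis=0, ddof=1) if s > 1 else np.zeros(loglik.shape[1])
    pointwise = -2.0 * (lppd_i - p_i)
    return {
        "waic": float(np.sum(pointwise)),
        "p_waic": float(np.sum(p_i)),
        "lppd": float(np.sum(lppd_i)),
        "pointwise": pointwise,
    }
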