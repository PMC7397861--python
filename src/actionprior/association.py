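"""Trait-association statistics.

Partial Pearson correlations adjusted for performance variability,
step-down Holm-Bonferroni correction, default-prior (JZS) correlation
Bayes factors, and power/sample-size computation for a two-sided Pearson
correlation test using the exact sampling distribution of r under a
bivariate normal population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats


@dataclass(frozen=True)
class PartialCorrResult:
    r: float
    df: int
    p: float
    bf10: float | None = None


def partial_correlation(x, y, z, bayes: bool = True) -> PartialCorrResult:
    """First-order partial Pearson correlation of x and y given z.

    Uses r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)); the
    two-sided p comes from t = r sqrt(df / (1-r^2)) with df = n - 3.
    Identical to correlating the residuals of x and y after regressing
    out z.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    for v in (x, y, z):
        if np.std(v) == 0:
            raise ValueError("inputs must be non-constant")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    df = n - 3
    t = r * np.sqrt(df / (1 - r ** 2))
    p = 2 * stats.t.sf(abs(t), df)
    bf = jzs_correlation_bf(r, n, n_covariates=1) if bayes else None
    return PartialCorrResult(r=float(r), df=df, p=float(p), bf10=bf)


def holm_adjust(pvals) -> np.ndarray:
    """Step-down Holm-Bonferroni adjusted p values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must be in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def jzs_correlation_bf(r: float, n: int, n_covariates: int = 0) -> float:
    """Default-prior Bayes factor for a (partial) Pearson correlation.

    Jeffreys's default test: the marginal likelihood of the observed r
    under a uniform prior on the population correlation rho, divided by
    its likelihood under rho = 0, computed by one-dimensional numerical
    integration of the exact sampling density of r.  For partial
    correlations the effective sample size is reduced by the number of
    covariates.  Returns BF10 (evidence for a nonzero correlation).
    """
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    n_eff = n - n_covariates
    if n_eff < 4:
        raise ValueError("effective sample size too small")
    num, err = integrate.quad(lambda rho: 0.5 * _r_density(r, rho, n_eff),
                              -1, 1, limit=200)
    denom = _r_density(r, 0.0, n_eff)
    if not np.isfinite(num) or denom <= 0 or (num > 0 and err / num > 1e-4):
        raise RuntimeError("Bayes factor integration failed")
    return float(num / denom)


def _r_density(r, rho, n):
    """Exact density of the sample correlation under a bivariate normal
    population with correlation rho."""
    lg = special.gammaln
    logc = (np.log(n - 2) + lg(n - 1) + 0.5 * (n - 1) * np.log1p(-rho ** 2)
            + 0.5 * (n - 4) * np.log1p(-r ** 2)
            - 0.5 * np.log(2 * np.pi) - lg(n - 0.5)
            - (n - 1.5) * np.log1p(-rho * r))
    return np.exp(logc) * special.hyp2f1(0.5, 0.5, (2 * n - 1) / 2, (rho * r + 1) / 2)


def correlation_power(rho: float, n: int, alpha: float = 0.05,
                      two_sided: bool = True) -> float:
    """Exact power of the Pearson correlation t test at sample size n."""
    if n < 4:
        raise ValueError("n must be at least 4")
    if two_sided:
        t_crit = stats.t.ppf(1 - alpha / 2, n - 2)
    else:
        t_crit = stats.t.ppf(1 - alpha, n - 2)
    r_crit = t_crit / np.sqrt(n - 2 + t_crit ** 2)
    upper, _ = integrate.quad(_r_density, r_crit, 1, args=(rho, n))
    if two_sided:
        lower, _ = integrate.quad(_r_density, -1, -r_crit, args=(rho, n))
    else:
        lower = 0.0
    return float(upper + lower)


def sample_size_for_correlation(rho: float, alpha: float = 0.05,
                                power: float = 0.80, two_sided: bool = True,
                                method: str = "exact", n_max: int = 100_000) -> int:
    """Smallest n at which the correlation test reaches the target power.

    ``method='exact'`` integrates the exact sampling distribution of r
    under rho; ``'fisher-z'`` uses the normal approximation
    n = ((z_alpha + z_beta) / atanh(rho))^2 + 3.
    """
    if not (0 < rho < 1 and 0 < alpha < 1 and 0 < power < 1):
        raise ValueError("rho, alpha and power must lie in (0, 1)")
    if method == "fisher-z":
        za = stats.norm.ppf(1 - alpha / 2) if two_sided else stats.norm.ppf(1 - alpha)
        zb = stats.norm.ppf(power)
        return int(np.ceil(((za + zb) / np.arctanh(rho)) ** 2 + 3))
    if method != "exact":
        raise ValueError("method must be 'exact' or 'fisher-z'")
    # bracket from the Fisher-z guess, then scan to the exact minimum
    guess = max(sample_size_for_correlation(rho, alpha, power, two_sided,
                                            method="fisher-z") - 10, 4)
    n = guess
    while n <= n_max and correlation_power(rho, n, alpha, two_sided) < power:
        n += 1
    if n > n_max:
        raise ValueError("no feasible n below n_max")
    while n > 4 and correlation_power(rho, n - 1, alpha, two_sided) >= power:
        n -= 1
    return int(n)


def trait_association_table(prior_sds: pd.Series, participants: pd.DataFrame,
                            perf_sd: pd.Series) -> pd.DataFrame:
    """Partial correlations of prior SD with each AMI scale, adjusted for
    performance variability, with Holm correction over the four-test
    family and JZS Bayes factors."""
    scales = ["ami_total", "ami_behavioral_activation",
              "ami_emotional_sensitivity", "ami_social_motivation"]
    idx = participants.set_index("participant_id")
    common = prior_sds.index.intersection(idx.index).intersection(perf_sd.index)
    x = prior_sds.loc[common].to_numpy()
    z = perf_sd.loc[common].to_numpy()
    rows = []
    for scale in scales:
        res = partial_correlation(x, idx.loc[common, scale].to_numpy(), z)
        rows.append({"scale": scale, "r": res.r, "df": res.df, "p": res.p,
                     "bf10": res.bf10})
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p"].to_numpy())
    return table
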