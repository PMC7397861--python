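"""Estimation-error ~ performance-error mixed models and conditional AIC.

The regression slope of estimation error on performance error identifies
the prior weighting w (slope = -w): -1 means full reliance on the prior
over sensory evidence, 0 means the prior is disregarded.  Ten candidate
random-effect structures are compared: a baseline with intercept and slope
varying by participant, plus adjustments of the intercept, the slope, or
both by effort, reward, or both, nested within participant.  Models are
fitted by maximum likelihood and compared with the conditional AIC
(conditional log-likelihood penalized by the effective degrees of freedom
from the trace of the mixed-model hat matrix).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

_ADJ = ("effort", "reward", "both")


@dataclass(frozen=True)
class LmmSpec:
    """Random-effect structure: which within-participant adjustments the
    intercept and slope receive ('none', 'effort', 'reward' or 'both')."""

    intercept_by: str = "none"
    slope_by: str = "none"

    @property
    def label(self) -> str:
        return f"int:{self.intercept_by}|slope:{self.slope_by}"

    def vc_formula(self) -> dict:
        vc = {}
        ints = {"effort": ["effort"], "reward": ["reward"],
                "both": ["effort", "reward"], "none": []}
        for f in ints[self.intercept_by]:
            vc[f"int_{f}"] = f"0 + C({f})"
        for f in ints[self.slope_by]:
            vc[f"slp_{f}"] = f"0 + C({f}):performance_error"
        return vc


def candidate_specs() -> list[LmmSpec]:
    """The ten candidate structures: baseline, intercept adjustments, slope
    adjustments, and matched intercept+slope adjustments."""
    specs = [LmmSpec("none", "none")]
    specs += [LmmSpec(a, "none") for a in _ADJ]
    specs += [LmmSpec("none", a) for a in _ADJ]
    specs += [LmmSpec(a, a) for a in _ADJ]
    return specs


@dataclass
class LmmFit:
    spec: LmmSpec
    intercept: float
    slope: float
    slope_ci: tuple
    participant_slopes: pd.Series
    loglik_marginal: float
    loglik_conditional: float
    edof: float
    caic: float
    scale: float
    converged: bool
    singular: bool
    n_obs: int
    #: (X, Z, G, y, fe_params) kept for hat-matrix cross-checks
    design: dict = field(default_factory=dict, repr=False)


def _is_degenerate(df: pd.DataFrame) -> tuple[bool, float, float]:
    """Detect an exactly linear estimation-error/performance-error relation
    (zero residual variance), where the mixed model is singular but the
    slope is determined exactly."""
    x = df["performance_error"].to_numpy(dtype=float)
    y = df["estimation_error"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    scale = max(np.var(y), np.var(x), 1.0)
    return bool(np.max(np.abs(resid)) < 1e-8 * np.sqrt(scale)), float(beta[0]), float(beta[1])


def _assemble_design(model, result) -> dict:
    """Build the stacked random-effect design Z and its covariance G from a
    fitted MixedLM, in original row order."""
    n = model.nobs
    groups = model.group_labels
    k_re = model.exog_re_li[0].shape[1] if model.exog_re_li is not None else 0
    vc = model.exog_vc
    n_vc = len(vc.names) if vc is not None else 0
    vc_cols = [np.asarray(vc.mats[j][0]).shape[1] for j in range(n_vc)]
    q_per_group = k_re + sum(vc_cols)
    Z = np.zeros((int(n), q_per_group * len(groups)))
    g_blocks = []
    # statsmodels reports cov_re and vcomp already on the response scale
    cov_re = np.atleast_2d(np.asarray(result.cov_re))
    for g_idx, g in enumerate(groups):
        rows = np.asarray(model.row_indices[g])
        col0 = g_idx * q_per_group
        if k_re:
            Z[rows, col0:col0 + k_re] = model.exog_re_li[g_idx]
        offset = k_re
        for j in range(n_vc):
            m = np.asarray(vc.mats[j][g_idx])
            Z[rows, col0 + offset:col0 + offset + m.shape[1]] = m
            offset += m.shape[1]
        blocks = [cov_re] if k_re else []
        for j in range(n_vc):
            blocks.append(result.vcomp[j] * np.eye(vc_cols[j]))
        g_blocks.append(_block_diag(blocks))
    G = _block_diag(g_blocks)
    return {"Z": Z, "G": G, "groups": groups, "k_re": k_re, "vc_cols": vc_cols}


def _block_diag(blocks):
    if not blocks:
        return np.zeros((0, 0))
    size = sum(b.shape[0] for b in blocks)
    out = np.zeros((size, size))
    i = 0
    for b in blocks:
        out[i:i + b.shape[0], i:i + b.shape[0]] = b
        i += b.shape[0]
    return out


def henderson_solve(X, Z, G, y, scale):
    """Solve Henderson's mixed-model equations for (beta_hat, b_hat) and
    return them with the effective degrees of freedom tr(H), where
    H = W C^{-1} W' maps y to the conditional fitted values."""
    W = np.hstack([X, Z])
    q = G.shape[0]
    jitter = 1e-10 * (np.trace(G) / max(q, 1) + scale)
    G_inv = np.linalg.inv(G + jitter * np.eye(q)) if q else np.zeros((0, 0))
    WtW = W.T @ W
    C = WtW.copy()
    p = X.shape[1]
    C[p:, p:] += scale * G_inv
    sol = np.linalg.solve(C, W.T @ y)
    edof = float(np.trace(np.linalg.solve(C, WtW)))
    return sol[:p], sol[p:], edof, W


def fit_weighting_model(trials: pd.DataFrame, spec: LmmSpec | None = None) -> LmmFit:
    """Fit one candidate mixed model to the estimation trials by ML.

    ``trials`` needs columns participant_id, effort, reward,
    performance_error, estimation_error (estimation trials only).  Returns
    fixed effects, per-participant conditional slopes, and the conditional
    log-likelihood / effective dof / cAIC.  Singular or perfectly
    collinear data are flagged and handled via the exact least-squares
    limit (zero random-effect variance).
    """
    spec = spec or LmmSpec()
    df = trials.dropna(subset=["estimation_error", "performance_error"]).copy()
    if df["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")

    degenerate, b0, b1 = _is_degenerate(df)
    if degenerate:
        log.warning("zero-residual data: returning exact least-squares fit (%s)", spec.label)
        pids = df["participant_id"].unique()
        n = len(df)
        p = 2
        ll = np.inf  # conditional density degenerates; cAIC not meaningful here
        return LmmFit(spec=spec, intercept=b0, slope=b1, slope_ci=(b1, b1),
                      participant_slopes=pd.Series(b1, index=pids),
                      loglik_marginal=ll, loglik_conditional=ll,
                      edof=float(p + 1), caic=-np.inf, scale=0.0,
                      converged=True, singular=True, n_obs=n)

    model = smf.mixedlm("estimation_error ~ performance_error", data=df,
                        groups="participant_id", re_formula="1 + performance_error",
                        vc_formula=spec.vc_formula() or None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=False, method=["lbfgs", "powell", "cg"])
    converged = bool(result.converged)

    design = _assemble_design(model, result)
    X = model.exog
    y = model.endog
    beta, b_hat, edof_raw, W = henderson_solve(X, design["Z"], design["G"], y, result.scale)
    fitted = W @ np.concatenate([beta, b_hat])
    resid = y - fitted
    n = len(y)
    sigma2 = result.scale
    ll_cond = float(-0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * np.dot(resid, resid) / sigma2)
    edof = edof_raw + 1.0  # + residual variance
    caic = -2.0 * ll_cond + 2.0 * edof

    # participant-level conditional slopes: fixed slope + participant random
    # slope + mean of that participant's condition-level slope offsets
    k_re = design["k_re"]
    q_per = k_re + sum(design["vc_cols"])
    slopes = {}
    for g_idx, g in enumerate(design["groups"]):
        b_g = b_hat[g_idx * q_per:(g_idx + 1) * q_per]
        s = result.fe_params["performance_error"] + (b_g[1] if k_re >= 2 else 0.0)
        offset = k_re
        for name, ncol in zip(spec.vc_formula(), design["vc_cols"]):
            if name.startswith("slp_"):
                s += float(np.mean(b_g[offset:offset + ncol]))
            offset += ncol
        slopes[g] = float(s)

    ci = result.conf_int().loc["performance_error"]
    singular = bool(np.any(np.diag(design["G"]) < 1e-10 * sigma2))
    if singular:
        log.warning("near-singular random-effect structure for %s", spec.label)
    return LmmFit(spec=spec, intercept=float(result.fe_params["Intercept"]),
                  slope=float(result.fe_params["performance_error"]),
                  slope_ci=(float(ci[0]), float(ci[1])),
                  participant_slopes=pd.Series(slopes),
                  loglik_marginal=float(result.llf),
                  loglik_conditional=ll_cond, edof=edof, caic=float(caic),
                  scale=float(sigma2), converged=converged, singular=singular,
                  n_obs=n,
                  design={"X": X, "Z": design["Z"], "G": design["G"], "y": y,
                          "scale": result.scale})


def conditional_aic(fit: LmmFit) -> float:
    """Conditional AIC of a fitted model: -2 * conditional log-likelihood
    + 2 * effective dof (hat-matrix trace + 1 for the residual variance)."""
    if not fit.converged:
        raise ValueError("conditional AIC undefined for a non-converged fit")
    return fit.caic


def select_weighting_model(trials: pd.DataFrame,
                           specs: list[LmmSpec] | None = None) -> tuple[LmmFit, pd.DataFrame]:
    """Fit all candidate structures and select the minimal-cAIC model.

    Non-converged candidates are excluded with a warning.  Returns the best
    fit and a table of cAIC differences to the best.
    """
    specs = specs if specs is not None else candidate_specs()
    fits = []
    for spec in specs:
        try:
            fit = fit_weighting_model(trials, spec)
        except (np.linalg.LinAlgError, ValueError) as exc:
            log.warning("candidate %s failed: %s", spec.label, exc)
            continue
        if not fit.converged:
            log.warning("candidate %s did not converge; excluded", spec.label)
            continue
        fits.append(fit)
    if not fits:
        raise RuntimeError("no candidate model converged")
    fits.sort(key=lambda f: f.caic)
    best = fits[0]
    table = pd.DataFrame({
        "spec": [f.spec.label for f in fits],
        "caic": [f.caic for f in fits],
        "delta_caic": [f.caic - best.caic for f in fits],
        "slope": [f.slope for f in fits],
    })
    return best, table
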