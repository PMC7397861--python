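"""Hierarchical Bayesian observer models of action-outcome perception.

On estimation trials the participant's reported final-ball-position
estimate is modelled as a precision-weighted combination of a Gaussian
prior and Gaussian sensory evidence,

    x_estimate = w * mu_prior + (1 - w) * mu_evidence,
    w = sigma_evidence^2 / (sigma_evidence^2 + sigma_prior^2),

with three variants:

* M1 — prior centred on the target; free sigma_prior, sigma_evidence.
* M2 — M1 plus a directional shift of the evidence mean,
  mu_evidence = x_true + s (free s).
* M3 — "observational" prior: mean and SD fixed to the participant's
  empirical performance distribution on basic trials; only
  sigma_evidence is free.

Trial-level stochasticity comes from the sensory sample, so the
likelihood of an observed estimate is Gaussian with mean
w*mu_prior + (1-w)*(x_true + s) and SD (1-w)*sigma_evidence.

Free parameters follow a three-level hierarchy (group -> participant ->
condition): condition-level values are Gaussian around a participant mean
(log scale for SDs), participant means are Gaussian around a group mean,
with half-Normal hyperpriors on all scale hyperparameters.  Estimation is
by a Gibbs sampler with conjugate updates for every location parameter
and slice sampling for scales, run as independent chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTruth, ObserverParams
from .mcmc import slice_sample_vec, split_rhat, waic
from .task import CONDITIONS

log = logging.getLogger(__name__)

VARIANTS = ("m1", "m2", "m3")

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class HyperPriors:
    """Weakly informative hyperpriors, in pixel units.

    Group means of log observer SDs are Gaussian around log(50) px with SD
    1.5 (covering a few px to several hundred px); the evidence shift's
    group mean is Gaussian around 0 with SD 50 px.  Between-participant and
    between-condition scale hyperparameters get half-Normal priors.
    """

    log_sigma_mean_loc: float = float(np.log(50.0))
    log_sigma_mean_scale: float = 1.5
    shift_mean_loc: float = 0.0
    shift_mean_scale: float = 50.0
    log_sigma_sd_scale: float = 1.0    # half-Normal scale for tau and kappa (log-SD params)
    shift_sd_scale: float = 20.0       # half-Normal scale for tau and kappa (shift)


def predictive_moments(sigma_prior, sigma_evidence, shift, mu_prior, x_true,
                       likelihood: str = "sensory"):
    """Mean and SD of the predicted estimate distribution for given
    observer parameters.  ``likelihood='sensory'`` propagates a single
    sensory sample, giving SD (1-w)*sigma_evidence; ``'posterior'`` uses
    the Bayes-posterior SD sqrt(sp^2 se^2 / (sp^2 + se^2))."""
    sp2 = np.square(sigma_prior)
    se2 = np.square(sigma_evidence)
    w = se2 / (se2 + sp2)
    mean = w * mu_prior + (1.0 - w) * (x_true + shift)
    if likelihood == "sensory":
        sd = (1.0 - w) * sigma_evidence
    elif likelihood == "posterior":
        sd = np.sqrt(sp2 * se2 / (sp2 + se2))
    else:
        raise ValueError(f"unknown likelihood mode {likelihood!r}")
    return mean, sd


def loglik_estimation_trial(params: ObserverParams, x_true: float,
                            x_estimate: float,
                            likelihood: str = "sensory") -> float:
    """Gaussian log density of one observed estimate under the observer."""
    mean, sd = predictive_moments(params.sigma_prior, params.sigma_evidence,
                                  params.shift_s, params.mu_prior, x_true,
                                  likelihood)
    if sd <= 0:
        raise ValueError("predictive SD must be positive")
    return float(-np.log(sd * _SQRT_2PI) - 0.5 * ((x_estimate - mean) / sd) ** 2)


# ---------------------------------------------------------------------------
# data layout


@dataclass
class _CellData:
    """Estimation trials arranged per participant x condition cell, padded
    for vectorized likelihood evaluation."""

    participants: list
    conditions: list                  # (effort, reward) per cell, aligned with cells
    cell_pid: np.ndarray              # participant index per cell
    cell_labels: list                 # (pid, effort, reward) per cell
    x_true: np.ndarray                # (C, T) padded
    x_est: np.ndarray                 # (C, T) padded
    mask: np.ndarray                  # (C, T) bool
    n_per_cell: np.ndarray            # (C,)
    mu_prior: np.ndarray              # (C,)
    fixed_sigma_prior: np.ndarray | None   # (C,) for M3
    trial_order: np.ndarray           # original row positions, len = total trials


def _prepare_cells(trials: pd.DataFrame, variant: str) -> _CellData:
    est = trials[trials["trial_type"] == "estimation"].dropna(subset=["x_estimate"])
    if est.empty:
        raise ValueError("no estimation trials with estimates")
    participants = list(dict.fromkeys(trials["participant_id"]))
    if len(participants) < 1:
        raise ValueError("no participants")
    basic = trials[trials["trial_type"] == "basic"]
    cells, labels, pid_idx = [], [], []
    for p_i, pid in enumerate(participants):
        for effort, reward in CONDITIONS:
            sub = est[(est["participant_id"] == pid) & (est["effort"] == effort)
                      & (est["reward"] == reward)]
            if sub.empty:
                continue
            cells.append(sub)
            labels.append((pid, effort, reward))
            pid_idx.append(p_i)
    tmax = max(len(c) for c in cells)
    C = len(cells)
    x_true = np.zeros((C, tmax))
    x_est = np.zeros((C, tmax))
    mask = np.zeros((C, tmax), dtype=bool)
    mu_prior = np.zeros(C)
    fixed_sp = np.zeros(C) if variant == "m3" else None
    order = []
    for i, (sub, (pid, effort, reward)) in enumerate(zip(cells, labels)):
        n = len(sub)
        x_true[i, :n] = sub["x_true"].to_numpy()
        x_est[i, :n] = sub["x_estimate"].to_numpy()
        mask[i, :n] = True
        order.append(sub.index.to_numpy())
        if variant == "m3":
            b = basic[(basic["participant_id"] == pid) & (basic["effort"] == effort)
                      & (basic["reward"] == reward)]
            if len(b) < 2:
                raise ValueError(f"observational prior needs basic trials in cell {pid}/{effort}/{reward}")
            mu_prior[i] = float(b["x_true"].mean())
            fixed_sp[i] = float(b["x_true"].std(ddof=1))
        else:
            mu_prior[i] = float(sub["x_target"].iloc[0])
    return _CellData(participants=participants, conditions=labels,
                     cell_pid=np.asarray(pid_idx), cell_labels=labels,
                     x_true=x_true, x_est=x_est, mask=mask,
                     n_per_cell=mask.sum(axis=1).astype(float),
                     mu_prior=mu_prior, fixed_sigma_prior=fixed_sp,
                     trial_order=np.concatenate(order))


# ---------------------------------------------------------------------------
# Gibbs sampler


def _cell_loglik(data: _CellData, log_sp, log_se, s, likelihood) -> np.ndarray:
    """Summed estimation-trial log likelihood per cell (vectorized)."""
    sp = np.exp(log_sp)[:, None]
    se = np.exp(log_se)[:, None]
    mean, sd = predictive_moments(sp, se, np.asarray(s)[:, None],
                                  data.mu_prior[:, None], data.x_true, likelihood)
    z = (data.x_est - mean) / sd
    ll = -np.log(sd * _SQRT_2PI) - 0.5 * z * z
    return np.sum(np.where(data.mask, ll, 0.0), axis=1)


class _Hierarchy:
    """One parameter's three-level hierarchy: cell values around participant
    means (SD kappa), participant means around a group mean mu (SD tau)."""

    def __init__(self, name, cell_pid, n_part, mean_loc, mean_scale, sd_scale, init, rng):
        self.name = name
        self.cell_pid = cell_pid
        self.n_part = n_part
        self.mean_loc = mean_loc
        self.mean_scale = mean_scale
        self.sd_scale = sd_scale
        self.cell = np.full(len(cell_pid), init) + 0.05 * mean_scale * rng.standard_normal(len(cell_pid))
        self.part = np.full(n_part, init) + 0.05 * mean_scale * rng.standard_normal(n_part)
        self.mu = init + 0.1 * mean_scale * rng.standard_normal()
        self.tau = 0.5 * sd_scale
        self.kappa = 0.5 * sd_scale
        counts = np.bincount(cell_pid, minlength=n_part).astype(float)
        self.counts = counts

    def cell_prior_logpdf(self, cell_values):
        m = self.part[self.cell_pid]
        return -0.5 * ((cell_values - m) / self.kappa) ** 2 - np.log(self.kappa)

    def update_locations(self, rng):
        # participant means: conjugate Gaussian given cell values and group level
        sums = np.bincount(self.cell_pid, weights=self.cell, minlength=self.n_part)
        prec = self.counts / self.kappa ** 2 + 1.0 / self.tau ** 2
        mean = (sums / self.kappa ** 2 + self.mu / self.tau ** 2) / prec
        self.part = mean + rng.standard_normal(self.n_part) / np.sqrt(prec)
        # group mean: conjugate Gaussian
        prec_mu = self.n_part / self.tau ** 2 + 1.0 / self.mean_scale ** 2
        mean_mu = (self.part.sum() / self.tau ** 2 + self.mean_loc / self.mean_scale ** 2) / prec_mu
        self.mu = mean_mu + rng.standard_normal() / np.sqrt(prec_mu)

    def update_scales(self, rng):
        # slice-sample log tau and log kappa
        part_dev = self.part - self.mu
        n_p = self.n_part

        def logf_tau(log_t):
            t = np.exp(log_t)
            return (-n_p * log_t - 0.5 * np.sum(part_dev ** 2) / t ** 2
                    - 0.5 * (t / self.sd_scale) ** 2 + log_t)

        self.tau = float(np.exp(slice_sample_vec(
            lambda v: np.array([logf_tau(v[0])]),
            np.array([np.log(self.tau)]), 1.0, rng)[0]))

        cell_dev = self.cell - self.part[self.cell_pid]
        n_c = len(self.cell)

        def logf_kappa(log_k):
            k = np.exp(log_k)
            return (-n_c * log_k - 0.5 * np.sum(cell_dev ** 2) / k ** 2
                    - 0.5 * (k / self.sd_scale) ** 2 + log_k)

        self.kappa = float(np.exp(slice_sample_vec(
            lambda v: np.array([logf_kappa(v[0])]),
            np.array([np.log(self.kappa)]), 1.0, rng)[0]))

    def asis_translate(self, rng, cell_loglik_fn):
        """Joint translation of the whole hierarchy (cells, participant
        means, group mean) against the data likelihood and the group-mean
        prior; all internal prior terms are translation invariant."""
        def logf(d_vec):
            d = d_vec[0]
            return np.array([
                np.sum(cell_loglik_fn(self.cell + d))
                - 0.5 * ((self.mu + d - self.mean_loc) / self.mean_scale) ** 2])

        d = float(slice_sample_vec(logf, np.zeros(1),
                                   0.2 * self.mean_scale, rng)[0])
        self.cell += d
        self.part += d
        self.mu += d

    def asis_translate_parts(self, rng, cell_loglik_fn):
        """Per-participant block translation: move one participant's cell
        values and participant mean together, against the data likelihood
        and the group-level prior.  When the condition-level spread kappa
        is small, cells and participant mean are almost rigidly coupled and
        single-site Gibbs steps become tiny; this block move restores
        mixing.  Participants are conditionally independent, so the update
        is vectorized."""
        def logf(d):
            cells = self.cell + d[self.cell_pid]
            ll = np.bincount(self.cell_pid, weights=cell_loglik_fn(cells),
                             minlength=self.n_part)
            return ll - 0.5 * ((self.part + d - self.mu) / self.tau) ** 2

        width = max(self.tau, 0.05 * self.mean_scale)
        d = slice_sample_vec(logf, np.zeros(self.n_part), width, rng)
        self.cell += d[self.cell_pid]
        self.part += d

    def asis_rescale(self, rng, cell_loglik_fn):
        """Interleaved non-centered (ancillarity-sufficiency) update of the
        scale hyperparameters: holding the standardized effects fixed,
        re-sample kappa against the data likelihood and tau against the
        cell-level prior.  Breaks the funnel-shaped coupling that makes
        centered scans sticky when group-level scales are small."""
        part_cell = self.part[self.cell_pid]
        e = (self.cell - part_cell) / self.kappa

        def logf_kappa(log_k):
            k = np.exp(log_k)
            return (np.sum(cell_loglik_fn(part_cell + k * e))
                    - 0.5 * (k / self.sd_scale) ** 2 + log_k)

        self.kappa = float(np.exp(slice_sample_vec(
            lambda v: np.array([logf_kappa(v[0])]),
            np.array([np.log(self.kappa)]), 1.0, rng)[0]))
        self.cell = part_cell + self.kappa * e

        u = (self.part - self.mu) / self.tau

        def logf_tau(log_t):
            t = np.exp(log_t)
            part = self.mu + t * u
            dev = self.cell - part[self.cell_pid]
            return (-0.5 * np.sum((dev / self.kappa) ** 2)
                    - 0.5 * (t / self.sd_scale) ** 2 + log_t)

        self.tau = float(np.exp(slice_sample_vec(
            lambda v: np.array([logf_tau(v[0])]),
            np.array([np.log(self.tau)]), 1.0, rng)[0]))
        self.part = self.mu + self.tau * u


@dataclass
class PosteriorFit:
    """Posterior draws, diagnostics and summaries of one model fit."""

    variant: str
    draws: dict                         # name -> (chains, samples) or (chains, samples, k)
    rhat: dict                          # flattened name -> R-hat
    cell_labels: list                   # (pid, effort, reward) per cell
    participants: list
    pointwise_loglik: np.ndarray        # (total draws, n estimation trials)
    waic: float
    p_waic: float
    pointwise_waic: np.ndarray
    cell_summary: pd.DataFrame          # posterior mean/sd per cell parameter
    participant_summary: pd.DataFrame   # participant-level posterior means
    likelihood: str
    seed: int
    n_trials: int
    trial_order: np.ndarray = field(repr=False, default=None)
    _data: _CellData = field(repr=False, default=None)

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())


def fit_hierarchical(trials: pd.DataFrame, variant: str = "m2",
                     chains: int = 4, samples: int = 500, warmup: int | None = None,
                     thin: int = 10, seed: int = 0, likelihood: str = "sensory",
                     hyperpriors: HyperPriors | None = None,
                     shared_shift: bool = False) -> PosteriorFit:
    """Fit one observer-model variant by Gibbs sampling.

    ``trials`` is a preprocessed trial table (basic trials are needed for
    the observational-prior variant).  ``warmup`` defaults to half of
    ``samples``; ``thin`` Gibbs scans are run per stored draw to
    decorrelate the chains.  ``shared_shift`` restricts the evidence shift to a single
    value per participant instead of per condition (by shrinking its
    condition-level spread; the default leaves it free per cell).
    Reproducible for a fixed seed.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    hp = hyperpriors or HyperPriors()
    warmup = samples // 2 if warmup is None else warmup
    data = _prepare_cells(trials, variant)
    C = len(data.cell_labels)
    n_part = len(data.participants)
    ss = np.random.SeedSequence([seed, 303])
    chain_seeds = ss.spawn(chains)

    store: dict[str, list] = {}
    total_ll = []

    for chain_rng_seq in chain_seeds:
        rng = np.random.default_rng(chain_rng_seq)
        h_sp = None if variant == "m3" else _Hierarchy(
            "log_sigma_prior", data.cell_pid, n_part, hp.log_sigma_mean_loc,
            hp.log_sigma_mean_scale, hp.log_sigma_sd_scale, hp.log_sigma_mean_loc, rng)
        h_se = _Hierarchy(
            "log_sigma_evidence", data.cell_pid, n_part, hp.log_sigma_mean_loc,
            hp.log_sigma_mean_scale, hp.log_sigma_sd_scale, hp.log_sigma_mean_loc, rng)
        h_s = None if variant != "m2" else _Hierarchy(
            "shift", data.cell_pid, n_part, hp.shift_mean_loc,
            hp.shift_mean_scale, hp.shift_sd_scale, 0.0, rng)

        log_sp = h_sp.cell if h_sp else np.log(data.fixed_sigma_prior)
        s_cell = h_s.cell if h_s else np.zeros(C)

        chain_draws: dict[str, list] = {}
        chain_ll = []
        n_scans = warmup + samples * thin
        for it in range(n_scans):
            # --- shift: conjugate Gaussian update per cell (M2) ----------
            if h_s is not None:
                sp = np.exp(log_sp)
                se = np.exp(h_se.cell)
                w = se ** 2 / (se ** 2 + sp ** 2)
                one_w = 1.0 - w
                resid = np.where(
                    data.mask,
                    data.x_est - w[:, None] * data.mu_prior[:, None]
                    - one_w[:, None] * data.x_true, 0.0)
                prec = data.n_per_cell / se ** 2 + 1.0 / h_s.kappa ** 2
                mean = (resid.sum(axis=1) / (one_w * se ** 2)
                        + h_s.part[data.cell_pid] / h_s.kappa ** 2) / prec
                h_s.cell = mean + rng.standard_normal(C) / np.sqrt(prec)
                s_cell = h_s.cell
                h_s.update_locations(rng)
                if shared_shift:
                    # pin the condition-level spread so each participant has
                    # effectively one shift; tau is still sampled
                    kappa_pinned = 1e-3 * hp.shift_sd_scale
                    h_s.kappa = kappa_pinned
                    h_s.update_scales(rng)
                    h_s.kappa = kappa_pinned
                else:
                    h_s.update_scales(rng)

            # --- log sigma_prior: slice update per cell (M1/M2) ----------
            if h_sp is not None:
                def logf_sp(v):
                    return _cell_loglik(data, v, h_se.cell, s_cell, likelihood) \
                        + h_sp.cell_prior_logpdf(v)
                h_sp.cell = slice_sample_vec(logf_sp, h_sp.cell, 0.5, rng)
                log_sp = h_sp.cell
                h_sp.update_locations(rng)
                h_sp.update_scales(rng)

            # --- log sigma_evidence: slice update per cell ---------------
            def logf_se(v):
                return _cell_loglik(data, log_sp, v, s_cell, likelihood) \
                    + h_se.cell_prior_logpdf(v)
            h_se.cell = slice_sample_vec(logf_se, h_se.cell, 0.5, rng)
            h_se.update_locations(rng)
            h_se.update_scales(rng)

            # joint diagonal update of (log_sp, log_se) per cell: moves along
            # the common-scale ridge (w fixed) that coordinate-wise slice
            # updates traverse slowly
            if h_sp is not None:
                base_sp, base_se = h_sp.cell.copy(), h_se.cell.copy()

                def logf_diag(delta):
                    return (_cell_loglik(data, base_sp + delta, base_se + delta,
                                         s_cell, likelihood)
                            + h_sp.cell_prior_logpdf(base_sp + delta)
                            + h_se.cell_prior_logpdf(base_se + delta))

                delta = slice_sample_vec(logf_diag, np.zeros(C), 0.5, rng)
                h_sp.cell = base_sp + delta
                h_se.cell = base_se + delta
                log_sp = h_sp.cell

            # interleaved non-centered rescaling of the hyper-scales, plus
            # whole-hierarchy and per-participant translations to
            # decorrelate the group mean and participant blocks
            if h_s is not None:
                h_s.asis_translate(rng, lambda v: _cell_loglik(
                    data, log_sp, h_se.cell, v, likelihood))
                h_s.asis_translate_parts(rng, lambda v: _cell_loglik(
                    data, log_sp, h_se.cell, v, likelihood))
                s_cell = h_s.cell
            if h_s is not None and not shared_shift:
                h_s.asis_rescale(rng, lambda v: _cell_loglik(
                    data, log_sp, h_se.cell, v, likelihood))
                s_cell = h_s.cell
            if h_sp is not None:
                h_sp.asis_rescale(rng, lambda v: _cell_loglik(
                    data, v, h_se.cell, s_cell, likelihood))
                h_sp.asis_translate_parts(rng, lambda v: _cell_loglik(
                    data, v, h_se.cell, s_cell, likelihood))
                log_sp = h_sp.cell
            h_se.asis_rescale(rng, lambda v: _cell_loglik(
                data, log_sp, v, s_cell, likelihood))
            h_se.asis_translate_parts(rng, lambda v: _cell_loglik(
                data, log_sp, v, s_cell, likelihood))

            if it >= warmup and (it - warmup) % thin == thin - 1:
                rec = {"log_sigma_evidence": h_se.cell.copy(),
                       "log_sigma_evidence_part": h_se.part.copy(),
                       "mu_log_sigma_evidence": h_se.mu,
                       "tau_log_sigma_evidence": h_se.tau,
                       "kappa_log_sigma_evidence": h_se.kappa}
                if h_sp is not None:
                    rec.update({"log_sigma_prior": h_sp.cell.copy(),
                                "log_sigma_prior_part": h_sp.part.copy(),
                                "mu_log_sigma_prior": h_sp.mu,
                                "tau_log_sigma_prior": h_sp.tau,
                                "kappa_log_sigma_prior": h_sp.kappa})
                if h_s is not None:
                    rec.update({"shift": h_s.cell.copy(),
                                "shift_part": h_s.part.copy(),
                                "mu_shift": h_s.mu, "tau_shift": h_s.tau,
                                "kappa_shift": h_s.kappa})
                for k, v in rec.items():
                    chain_draws.setdefault(k, []).append(v)
                chain_ll.append(_pointwise_loglik(data, log_sp, h_se.cell,
                                                  s_cell, likelihood))
        for k, v in chain_draws.items():
            store.setdefault(k, []).append(np.asarray(v))
        total_ll.append(np.asarray(chain_ll))

    draws = {k: np.stack(v) for k, v in store.items()}   # (chains, samples, ...)
    rhat = _rhat_all(draws)
    bad = {k: v for k, v in rhat.items() if not np.isfinite(v)}
    if bad:
        raise RuntimeError(f"sampling failed; non-finite R-hat for {sorted(bad)}")

    ll = np.concatenate(total_ll, axis=0)                # (chains*samples, n_trials)
    w = waic(ll)
    cell_summary, part_summary = _summaries(draws, data)
    return PosteriorFit(variant=variant, draws=draws, rhat=rhat,
                        cell_labels=data.cell_labels, participants=data.participants,
                        pointwise_loglik=ll, waic=w["waic"], p_waic=w["p_waic"],
                        pointwise_waic=w["pointwise"], cell_summary=cell_summary,
                        participant_summary=part_summary, likelihood=likelihood,
                        seed=seed, n_trials=ll.shape[1],
                        trial_order=data.trial_order, _data=data)


def _pointwise_loglik(data: _CellData, log_sp, log_se, s, likelihood) -> np.ndarray:
    sp = np.exp(log_sp)[:, None]
    se = np.exp(log_se)[:, None]
    mean, sd = predictive_moments(sp, se, np.asarray(s)[:, None],
                                  data.mu_prior[:, None], data.x_true, likelihood)
    z = (data.x_est - mean) / sd
    ll = -np.log(sd * _SQRT_2PI) - 0.5 * z * z
    return ll[data.mask]


def _rhat_all(draws: dict) -> dict:
    out = {}
    for name, arr in draws.items():
        if arr.ndim == 2:
            out[name] = split_rhat(arr)
        else:
            for j in range(arr.shape[2]):
                out[f"{name}[{j}]"] = split_rhat(arr[:, :, j])
    return out


def _summaries(draws: dict, data: _CellData) -> tuple[pd.DataFrame, pd.DataFrame]:
    C = len(data.cell_labels)
    flat = {k: v.reshape(-1, *v.shape[2:]) for k, v in draws.items()}
    rows = []
    for i, (pid, effort, reward) in enumerate(data.cell_labels):
        row = {"participant_id": pid, "effort": effort, "reward": reward}
        if "log_sigma_prior" in flat:
            sp = np.exp(flat["log_sigma_prior"][:, i])
            row["sigma_prior_mean"], row["sigma_prior_sd"] = sp.mean(), sp.std()
        else:
            row["sigma_prior_mean"] = data.fixed_sigma_prior[i]
            row["sigma_prior_sd"] = 0.0
        se = np.exp(flat["log_sigma_evidence"][:, i])
        row["sigma_evidence_mean"], row["sigma_evidence_sd"] = se.mean(), se.std()
        if "shift" in flat:
            s = flat["shift"][:, i]
            row["shift_mean"], row["shift_sd"] = s.mean(), s.std()
            row["shift_q025"], row["shift_q975"] = np.quantile(s, [0.025, 0.975])
        rows.append(row)
    cell = pd.DataFrame(rows)

    part_rows = []
    for j, pid in enumerate(data.participants):
        row = {"participant_id": pid}
        if "log_sigma_prior_part" in flat:
            row["sigma_prior_mean"] = float(np.exp(flat["log_sigma_prior_part"][:, j]).mean())
        else:
            row["sigma_prior_mean"] = float(
                cell.loc[cell["participant_id"] == pid, "sigma_prior_mean"].mean())
        row["sigma_evidence_mean"] = float(np.exp(flat["log_sigma_evidence_part"][:, j]).mean())
        if "shift_part" in flat:
            row["shift_mean"] = float(flat["shift_part"][:, j].mean())
        part_rows.append(row)
    return cell, pd.DataFrame(part_rows)


# ---------------------------------------------------------------------------
# model comparison, checks, extraction


def compute_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction for one parameter's draws
    (chains x samples)."""
    return split_rhat(draws)


@dataclass
class ModelComparison:
    table: pd.DataFrame
    best: str


def compare_waic(fits: list[PosteriorFit]) -> ModelComparison:
    """Pairwise WAIC differences with SEs from pointwise contributions.

    All fits must cover the identical estimation trials.  SE of a
    difference is sd(pointwise differences) * sqrt(n); the lowest-WAIC
    model is flagged best.
    """
    n = {f.n_trials for f in fits}
    if len(n) != 1:
        raise ValueError("fits cover different trial sets")
    for f in fits[1:]:
        if not np.array_equal(f.trial_order, fits[0].trial_order):
            raise ValueError("fits cover different trial sets")
    rows = []
    for a in fits:
        for b in fits:
            d = a.pointwise_waic - b.pointwise_waic
            rows.append({"model_a": a.variant, "model_b": b.variant,
                         "delta_waic": float(d.sum()),
                         "se_delta_waic": float(d.std(ddof=1) * np.sqrt(len(d)))
                         if a is not b else 0.0})
    best = min(fits, key=lambda f: f.waic).variant
    return ModelComparison(table=pd.DataFrame(rows), best=best)


def posterior_predictive(fit: PosteriorFit, n_rep: int = 100, seed: int = 0,
                         interval: float = 0.95) -> dict:
    """Simulate replicated estimates from the posterior predictive and
    report central-interval coverage of the observed estimates."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    data = fit._data
    flat = {k: v.reshape(-1, *v.shape[2:]) for k, v in fit.draws.items()}
    n_draws = next(iter(flat.values())).shape[0]
    idx = rng.choice(n_draws, size=n_rep, replace=n_rep > n_draws)
    reps = []
    for i in idx:
        log_sp = flat["log_sigma_prior"][i] if "log_sigma_prior" in flat \
            else np.log(data.fixed_sigma_prior)
        log_se = flat["log_sigma_evidence"][i]
        s = flat["shift"][i] if "shift" in flat else np.zeros(len(data.cell_labels))
        mean, sd = predictive_moments(np.exp(log_sp)[:, None], np.exp(log_se)[:, None],
                                      s[:, None], data.mu_prior[:, None],
                                      data.x_true, fit.likelihood)
        sim = rng.normal(mean, np.broadcast_to(sd, mean.shape))
        reps.append(sim[data.mask])
    reps = np.asarray(reps)                       # (n_rep, n_trials)
    lo, hi = np.quantile(reps, [(1 - interval) / 2, 1 - (1 - interval) / 2], axis=0)
    obs = data.x_est[data.mask]
    covered = (obs >= lo) & (obs <= hi)
    cond_per_trial = np.repeat(
        np.arange(len(data.cell_labels)), data.n_per_cell.astype(int))
    cond_cov = {}
    for (effort, reward) in {(e, r) for _, e, r in data.cell_labels}:
        m = np.array([fit.cell_labels[c][1:] == (effort, reward) for c in cond_per_trial])
        cond_cov[f"{effort}|{reward}"] = float(covered[m].mean())
    return {"replicates": reps, "coverage": float(covered.mean()),
            "coverage_by_condition": cond_cov, "interval": interval}


def extract_prior_sd(fit: PosteriorFit) -> dict:
    """Posterior-mean prior SDs: per participant and per participant x
    condition cell."""
    return {
        "participant": fit.participant_summary.set_index("participant_id")["sigma_prior_mean"],
        "cell": fit.cell_summary[["participant_id", "effort", "reward", "sigma_prior_mean"]],
    }


def normalized_prior_sd(sigma_prior, perf_sd):
    """Scale-free prior narrowness: sigma_prior / (sigma_prior + perf_sd)."""
    sigma_prior = np.asarray(sigma_prior, dtype=float)
    perf_sd = np.asarray(perf_sd, dtype=float)
    if np.any(perf_sd <= 0):
        raise ValueError("performance SD must be positive")
    return sigma_prior / (sigma_prior + perf_sd)


def parameter_recovery_report(truth: CohortTruth, fit: PosteriorFit,
                              min_corr: float = 0.7) -> dict:
    """Score a fit on simulator output against the generating parameters.

    Correlation and RMSE of posterior means vs truth across participant x
    condition cells and across participants; pass/fail on the
    participant-level prior-SD correlation threshold."""
    truth_cells = truth.params.set_index(["participant_id", "effort", "reward"])
    fit_cells = fit.cell_summary.set_index(["participant_id", "effort", "reward"])
    if not set(fit_cells.index) <= set(truth_cells.index):
        raise ValueError("fit contains cells absent from the ground truth")
    merged = fit_cells.join(truth_cells, how="inner", rsuffix="_true")
    out = {"cells": {}, "participants": {}}
    pairs = [("sigma_prior_mean", "sigma_prior"),
             ("sigma_evidence_mean", "sigma_evidence")]
    if "shift_mean" in merged:
        pairs.append(("shift_mean", "shift_s"))
    for est_col, true_col in pairs:
        e, t = merged[est_col].to_numpy(), merged[true_col].to_numpy()
        out["cells"][true_col] = {
            "corr": float(np.corrcoef(e, t)[0, 1]),
            "rmse": float(np.sqrt(np.mean((e - t) ** 2)))}
    part_truth = truth.params.groupby("participant_id").agg(
        sigma_prior=("sigma_prior", lambda s: float(np.exp(np.mean(np.log(s))))),
        sigma_evidence=("sigma_evidence", lambda s: float(np.exp(np.mean(np.log(s))))),
        shift_s=("shift_s", "mean"))
    part = fit.participant_summary.set_index("participant_id").join(part_truth)
    for est_col, true_col in [("sigma_prior_mean", "sigma_prior"),
                              ("sigma_evidence_mean", "sigma_evidence")] + (
                                  [("shift_mean", "shift_s")] if "shift_mean" in part else []):
        e, t = part[est_col].to_numpy(), part[true_col].to_numpy()
        out["participants"][true_col] = {
            "corr": float(np.corrcoef(e, t)[0, 1]),
            "rmse": float(np.sqrt(np.mean((e - t) ** 2)))}
    out["pass"] = bool(out["participants"]["sigma_prior"]["corr"] >= min_corr)
    out["threshold"] = min_corr
    return out
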