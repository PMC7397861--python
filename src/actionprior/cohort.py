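"""Synthetic cohorts with known ground truth.

Generates trial-level datasets with the statistical structure the analysis
assumes: per-participant force production with an effort-dependent
undershoot bias and variability, performance estimates produced by a
precision-weighted Bayesian observer (prior centred on the target, sensory
evidence centred on the true outcome plus a directional shift), and a trait
apathy score whose partial correlation with prior width — controlling for
performance variability — is set by construction.  Every generative
parameter is recorded so that model fits can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .task import CONDITIONS, TaskConfig, Trial, force_to_position, generate_schedule


@dataclass(frozen=True)
class ObserverParams:
    """Bayesian-observer parameters for one participant x condition cell.

    ``sigma_prior`` and ``sigma_evidence`` are the SDs (px) of the prior
    over the final ball position and of the sensory evidence; ``shift_s``
    is a signed shift (px) of the evidence mean away from the true
    position; ``mu_prior`` is the prior mean (the target position, or the
    empirical performance mean under the observational-prior variant).
    """

    sigma_prior: float
    sigma_evidence: float
    shift_s: float
    mu_prior: float

    def __post_init__(self) -> None:
        if self.sigma_prior <= 0 or self.sigma_evidence <= 0:
            raise ValueError("sigma_prior and sigma_evidence must be positive")

    @property
    def weight(self) -> float:
        """Precision-derived prior weight w = sigma_e^2 / (sigma_e^2 + sigma_p^2)."""
        return self.sigma_evidence ** 2 / (self.sigma_evidence ** 2 + self.sigma_prior ** 2)

    def mu_evidence(self, x_true: float) -> float:
        return x_true + self.shift_s

    def predicted_estimate(self, x_true: float) -> float:
        w = self.weight
        return w * self.mu_prior + (1.0 - w) * self.mu_evidence(x_true)


@dataclass(frozen=True)
class GenerativeConfig:
    """Population-level generative settings of the synthetic cohort.

    Location/scale pairs of log-normal population distributions for the
    observer SDs (px), a Gaussian population for the evidence shift (px),
    and force-production bias/SD (fractions of maximum force) per effort
    level with a reward improvement.  Defaults give a group-mean prior
    weight w of about 0.7, prior SDs well below the corresponding
    performance SDs, an undershoot bias that grows with effort, and higher
    variability under high effort.
    """

    mean_log_sigma_prior: float = float(np.log(45.0))
    sd_log_sigma_prior: float = 0.4          # between participants
    mean_log_sigma_evidence: float = float(np.log(70.0))
    sd_log_sigma_evidence: float = 0.4
    sd_log_sigma_condition: float = 0.15     # within participant, between conditions
    mean_shift: float = -15.0
    sd_shift: float = 8.0
    sd_shift_condition: float = 4.0
    #: force bias (fraction of max force) by effort; negative = undershoot
    force_bias: dict = field(default_factory=lambda: {"low": -0.01, "high": -0.04})
    #: reward reduces |bias| by this amount (fraction of max force)
    reward_bias_gain: float = 0.005
    #: force SD (fraction of max force) by effort
    force_sd: dict = field(default_factory=lambda: {"low": 0.05, "high": 0.08})
    reward_sd_gain: float = 0.005
    sd_log_force_sd: float = 0.15            # between-participant spread of force SD
    sd_force_bias: float = 0.01              # between-participant spread of bias
    max_force_mean_n: float = 25.0
    max_force_sd_n: float = 6.0
    trait_link_rho: float = 0.37
    ami_means: dict = field(default_factory=lambda: {
        "behavioral_activation": 1.5, "emotional_sensitivity": 1.5,
        "social_motivation": 1.2})
    ami_sd: float = 0.7


@dataclass
class CohortTruth:
    """Ground truth of a synthetic cohort.

    ``params``: one row per participant x condition with the observer
    parameters and force-production bias/SD; ``participants``: one row per
    participant with maximum force and AMI scores; ``generative``: the
    population settings the cohort was drawn from.
    """

    params: pd.DataFrame
    participants: pd.DataFrame
    generative: GenerativeConfig
    task: TaskConfig

    def to_json(self, path) -> None:
        io.write_json({
            "params": self.params.to_dict(orient="records"),
            "participants": self.participants.to_dict(orient="records"),
            "generative": {k: v for k, v in self.generative.__dict__.items()},
            "task": self.task.to_dict(),
        }, path)

    @classmethod
    def from_json(cls, path) -> "CohortTruth":
        d = io.read_json(path)
        return cls(params=pd.DataFrame(d["params"]),
                   participants=pd.DataFrame(d["participants"]),
                   generative=GenerativeConfig(**d["generative"]),
                   task=TaskConfig.from_dict(d["task"]))


def _participant_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"p{i + 1:0{width}d}" for i in range(n)]


def sample_cohort(n_participants: int = 47,
                  task: TaskConfig | None = None,
                  generative: GenerativeConfig | None = None,
                  seed: int = 0) -> CohortTruth:
    """Draw a cohort's ground-truth parameters from the population model.

    Observer SDs follow a two-level log-normal hierarchy (participant mean,
    condition-level variation around it); the evidence shift follows the
    analogous Gaussian hierarchy.  The AMI behavioural-activation score is
    constructed so that its partial correlation with the participant-mean
    prior SD, adjusting for performance variability, targets
    ``generative.trait_link_rho``.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    task = task or TaskConfig()
    gen = generative or GenerativeConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    ids = _participant_ids(n_participants)

    lsp_part = rng.normal(gen.mean_log_sigma_prior, gen.sd_log_sigma_prior, n_participants)
    lse_part = rng.normal(gen.mean_log_sigma_evidence, gen.sd_log_sigma_evidence, n_participants)
    s_part = rng.normal(gen.mean_shift, gen.sd_shift, n_participants)
    bias_part = rng.normal(0.0, gen.sd_force_bias, n_participants)
    lsd_part = rng.normal(0.0, gen.sd_log_force_sd, n_participants)
    max_force = np.maximum(rng.normal(gen.max_force_mean_n, gen.max_force_sd_n,
                                      n_participants), 5.0)

    rows = []
    for i, pid in enumerate(ids):
        for effort, reward in CONDITIONS:
            lsp = rng.normal(lsp_part[i], gen.sd_log_sigma_condition)
            lse = rng.normal(lse_part[i], gen.sd_log_sigma_condition)
            s = rng.normal(s_part[i], gen.sd_shift_condition)
            bias = gen.force_bias[effort] + bias_part[i] \
                + (gen.reward_bias_gain if reward == "yes" else 0.0) * np.sign(-gen.force_bias[effort])
            sd = max(gen.force_sd[effort] * np.exp(lsd_part[i])
                     - (gen.reward_sd_gain if reward == "yes" else 0.0), 0.005)
            rows.append({
                "participant_id": pid, "effort": effort, "reward": reward,
                "sigma_prior": float(np.exp(lsp)),
                "sigma_evidence": float(np.exp(lse)),
                "shift_s": float(s),
                "mu_prior": task.target_x(effort),
                "force_bias": float(bias),
                "force_sd": float(sd),
            })
    params = pd.DataFrame(rows)

    # trait link uses participant-level mean prior SD vs an analytic proxy of
    # performance variability in px (force SD mapped through the mean slope
    # of the force->position map across conditions)
    mean_sigma_prior = params.groupby("participant_id", sort=False)["sigma_prior"].mean().to_numpy()
    perf_proxy = params.groupby("participant_id", sort=False)["force_sd"].mean().to_numpy()
    ami = link_trait(mean_sigma_prior, perf_proxy, gen.trait_link_rho,
                     seed=int(rng.integers(2 ** 31)), generative=gen)
    participants = pd.DataFrame({
        "participant_id": ids,
        "max_force_n": max_force,
        "ami_behavioral_activation": ami["behavioral_activation"],
        "ami_emotional_sensitivity": ami["emotional_sensitivity"],
        "ami_social_motivation": ami["social_motivation"],
        "ami_total": ami["total"],
    })
    return CohortTruth(params=params, participants=participants, generative=gen, task=task)


def link_trait(sigma_priors: np.ndarray, performance_sds: np.ndarray,
               rho: float, seed: int = 0,
               generative: GenerativeConfig | None = None) -> dict:
    """Construct AMI subscale scores whose behavioural-activation component
    has population partial correlation ``rho`` with ``sigma_priors`` given
    ``performance_sds``.  Scores are rescaled into the 0-4 item range; the
    other two subscales are independent noise."""
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    gen = generative or GenerativeConfig()
    rng = np.random.default_rng(seed)
    x = np.asarray(sigma_priors, dtype=float)
    z = np.asarray(performance_sds, dtype=float)
    n = len(x)
    zc = (z - z.mean()) / (z.std() or 1.0)
    # residualize prior SD on the performance-variability control
    beta = np.dot(zc, x - x.mean()) / np.dot(zc, zc)
    rx = x - x.mean() - beta * zc
    rx = rx / (rx.std() or 1.0)
    eps = rng.standard_normal(n)
    eps -= zc * np.dot(zc, eps) / np.dot(zc, zc)     # keep noise orthogonal to control
    eps = eps / (eps.std() or 1.0)
    latent = rho * rx + np.sqrt(1.0 - rho ** 2) * eps + 0.3 * zc
    latent = (latent - latent.mean()) / (latent.std() or 1.0)

    def to_scale(zscores, mean):
        return np.clip(mean + gen.ami_sd * np.asarray(zscores), 0.0, 4.0)

    ba = to_scale(latent, gen.ami_means["behavioral_activation"])
    es = to_scale(rng.standard_normal(n), gen.ami_means["emotional_sensitivity"])
    sm = to_scale(rng.standard_normal(n), gen.ami_means["social_motivation"])
    return {"behavioral_activation": ba, "emotional_sensitivity": es,
            "social_motivation": sm, "total": (ba + es + sm) / 3.0}


def simulate_trials(truth: CohortTruth, seed: int = 0,
                    task: TaskConfig | None = None) -> pd.DataFrame:
    """Simulate the full trial table for a cohort.

    Per trial the force response is Gaussian around the nominal effort force
    plus the cell's bias; the final position follows the deterministic
    force->position map.  On estimation trials a sensory sample
    x_s ~ Normal(x_true + s, sigma_evidence) is drawn and the reported
    estimate is the precision-weighted combination w*mu_prior + (1-w)*x_s.
    """
    task = task or truth.task
    ss = np.random.SeedSequence([seed, 202])
    cell = truth.params.set_index(["participant_id", "effort", "reward"])
    frames = []
    for pid, child in zip(truth.participants["participant_id"],
                          ss.spawn(len(truth.participants))):
        rng = np.random.default_rng(child)
        schedule = generate_schedule(task, seed=int(rng.integers(2 ** 31)),
                                     participant_id=pid)
        rows = []
        for t in schedule:
            p = cell.loc[(pid, t.effort, t.reward)]
            f_nom = task.effort_fractions[t.effort]
            force = max(rng.normal(f_nom + p["force_bias"], p["force_sd"]), 0.0)
            x_true = float(force_to_position(force, t.effort, task))
            row = Trial(
                participant_id=pid, block=t.block, trial_in_block=t.trial_in_block,
                effort=t.effort, reward=t.reward, trial_type=t.trial_type,
                force_response=force,
                force_error=(force - f_nom) * 100.0,
                x_true=x_true, x_target=t.x_target,
                performance_error=x_true - t.x_target)
            if t.trial_type == "estimation":
                w = p["sigma_evidence"] ** 2 / (p["sigma_evidence"] ** 2 + p["sigma_prior"] ** 2)
                x_s = rng.normal(x_true + p["shift_s"], p["sigma_evidence"])
                row.x_estimate = w * p["mu_prior"] + (1.0 - w) * x_s
                row.estimation_error = row.x_estimate - x_true
            rows.append(row)
        frames.append(io.trials_to_frame(rows))
    return pd.concat(frames, ignore_index=True)
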