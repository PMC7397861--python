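"""Shared fixtures: reduced task layouts and a session-scoped desk-scale
hierarchical fit reused by the convergence/recovery/calibration tests."""

from __future__ import annotations

import numpy as np
import pytest

import actionprior as ap


def reduced_task(blocks_per_condition: int = 2) -> ap.TaskConfig:
    """A shortened task: blocks of 15 trials (10 basic + 5 estimation),
    same geometry as the full task."""
    return ap.TaskConfig(n_blocks=4 * blocks_per_condition, trials_per_block=15,
                         basic_per_block=10, estimation_per_block=5,
                         blocks_per_condition=blocks_per_condition)


def fixed_weight_generative(w: float, sigma_evidence: float = 70.0,
                            shift: float = 0.0) -> ap.GenerativeConfig:
    """Generative settings with no between-participant or between-condition
    spread in the observer parameters, so the prior weight w is exact."""
    sigma_prior = sigma_evidence * np.sqrt((1 - w) / w)
    return ap.GenerativeConfig(
        mean_log_sigma_prior=float(np.log(sigma_prior)),
        sd_log_sigma_prior=0.0,
        mean_log_sigma_evidence=float(np.log(sigma_evidence)),
        sd_log_sigma_evidence=0.0,
        sd_log_sigma_condition=0.0,
        mean_shift=shift, sd_shift=0.0, sd_shift_condition=0.0)


@pytest.fixture(scope="session")
def desk_cohort():
    """30 participants x 80 estimation trials from the shifted-evidence
    generative model at default population settings."""
    truth = ap.sample_cohort(30, seed=11)
    trials = ap.simulate_trials(truth, seed=12, task=reduced_task(4))
    trials, _ = ap.preprocess(trials)
    return truth, trials


@pytest.fixture(scope="session")
def desk_fit_m2(desk_cohort):
    """Hierarchical shifted-evidence fit at reduced sampler scale
    (4 chains x 500 stored draws)."""
    _, trials = desk_cohort
    return ap.fit_hierarchical(trials, "m2", chains=4, samples=500,
                               warmup=500, seed=13)


@pytest.fixture(scope="session")
def small_cohort():
    truth = ap.sample_cohort(8, seed=3)
    trials = ap.simulate_trials(truth, seed=4, task=reduced_task(2))
    return truth, trials
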