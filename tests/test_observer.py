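"""Observer-model likelihood, hierarchical fitting, WAIC comparison,
posterior predictive calibration and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

import actionprior as ap
from actionprior.observer import ModelComparison, predictive_moments
from conftest import fixed_weight_generative, reduced_task


def _single_cell_trials(sigma_prior, sigma_evidence, shift, n, seed,
                        target=512.0):
    """Estimation trials for one participant in one condition with known
    observer parameters."""
    rng = np.random.default_rng(seed)
    x_true = rng.normal(target - 30.0, 120.0, n).clip(128, 1280)
    w = sigma_evidence ** 2 / (sigma_evidence ** 2 + sigma_prior ** 2)
    x_s = rng.normal(x_true + shift, sigma_evidence)
    x_est = w * target + (1 - w) * x_s
    return pd.DataFrame({
        "participant_id": "p01", "block": 1, "trial_in_block": np.arange(2, n + 2),
        "effort": "low", "reward": "no", "trial_type": "estimation",
        "force_response": 0.35, "force_error": 0.0,
        "x_true": x_true, "x_target": target,
        "performance_error": x_true - target,
        "x_estimate": x_est, "estimation_error": x_est - x_true,
    })


class TestTrialLikelihood:
    def test_closed_form_value(self):
        params = ap.ObserverParams(sigma_prior=30.0, sigma_evidence=60.0,
                                   shift_s=-10.0, mu_prior=512.0)
        w = 60.0 ** 2 / (60.0 ** 2 + 30.0 ** 2)
        mean = w * 512.0 + (1 - w) * (600.0 - 10.0)
        sd = (1 - w) * 60.0
        expected = -0.5 * np.log(2 * np.pi * sd ** 2) \
            - 0.5 * ((550.0 - mean) / sd) ** 2
        got = ap.loglik_estimation_trial(params, x_true=600.0, x_estimate=550.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_flat_prior_limit(self):
        mean, sd = predictive_moments(1e9, 60.0, 0.0, 512.0, 640.0)
        assert mean == pytest.approx(640.0, abs=1e-3)
        assert sd == pytest.approx(60.0, rel=1e-6)

    def test_equal_sigmas_midpoint(self):
        mean, sd = predictive_moments(50.0, 50.0, -10.0, 512.0, 600.0)
        assert mean == pytest.approx((512.0 + 590.0) / 2)
        assert sd == pytest.approx(25.0)

    def test_posterior_sd_mode(self):
        _, sd = predictive_moments(30.0, 60.0, 0.0, 512.0, 600.0,
                                   likelihood="posterior")
        assert sd == pytest.approx(np.sqrt(30 ** 2 * 60 ** 2 / (30 ** 2 + 60 ** 2)))

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            ap.ObserverParams(sigma_prior=-1.0, sigma_evidence=60.0,
                              shift_s=0.0, mu_prior=512.0)

    def test_shift_zero_reduces_shifted_model_to_plain(self):
        # the shifted-evidence model nests the plain model at s = 0
        plain = ap.ObserverParams(40.0, 70.0, 0.0, 512.0)
        for x_true, x_est in [(600.0, 550.0), (450.0, 470.0)]:
            a = ap.loglik_estimation_trial(plain, x_true, x_est)
            m, s = predictive_moments(40.0, 70.0, 0.0, 512.0, x_true)
            b = float(-0.5 * np.log(2 * np.pi * s ** 2) - 0.5 * ((x_est - m) / s) ** 2)
            assert a == pytest.approx(b)


class TestHierarchicalFit:
    def test_single_participant_recovery(self):
        trials = _single_cell_trials(40.0, 60.0, 0.0, n=400, seed=0)
        fit = ap.fit_hierarchical(trials, "m1", chains=2, samples=250,
                                  warmup=250, thin=3, seed=1)
        sp = fit.cell_summary["sigma_prior_mean"].iloc[0]
        assert sp == pytest.approx(40.0, rel=0.15)

    def test_null_shift_posterior_covers_zero(self):
        gen = fixed_weight_generative(0.7, shift=0.0)
        truth = ap.sample_cohort(8, generative=gen, seed=2)
        trials = ap.simulate_trials(truth, seed=3, task=reduced_task(2))
        fit = ap.fit_hierarchical(trials, "m2", chains=2, samples=250,
                                  warmup=250, thin=3, seed=4)
        mu_s = fit.draws["mu_shift"].ravel()
        lo, hi = np.quantile(mu_s, [0.025, 0.975])
        assert lo < 0.0 < hi

    def test_invalid_variant_rejected(self):
        with pytest.raises(ValueError):
            ap.fit_hierarchical(_single_cell_trials(40, 60, 0, 10, 0),
                                variant="m4")

    def test_observational_prior_uses_basic_trial_moments(self, small_cohort):
        _, trials = small_cohort
        fit = ap.fit_hierarchical(trials, "m3", chains=2, samples=50,
                                  warmup=50, thin=1, seed=5)
        pid, effort, reward = fit.cell_labels[0]
        basic = trials[(trials["participant_id"] == pid)
                       & (trials["effort"] == effort)
                       & (trials["reward"] == reward)
                       & (trials["trial_type"] == "basic")]
        row = fit.cell_summary.iloc[0]
        assert row["sigma_prior_mean"] == pytest.approx(basic["x_true"].std(ddof=1))
        assert row["sigma_prior_sd"] == 0.0


class TestDeskScaleFit:
    """Checks that share the session-scoped reduced-scale fit."""

    def test_convergence_diagnostics(self, desk_fit_m2):
        # split R-hat is bounded below by sqrt((n-1)/n) for well-mixed chains
        assert all(v >= 0.99 for v in desk_fit_m2.rhat.values())
        assert np.isfinite(desk_fit_m2.waic)

    def test_prior_sd_smaller_than_performance_sd(self, desk_cohort, desk_fit_m2):
        _, trials = desk_cohort
        perf_sd = ap.summarize_performance(trials)["participant_sd"]
        prior_sd = ap.extract_prior_sd(desk_fit_m2)["participant"]
        frac = (prior_sd.reindex(perf_sd.index) < perf_sd).mean()
        assert frac > 0.5

    def test_recovery_negative_control(self, desk_cohort, desk_fit_m2):
        truth, _ = desk_cohort
        rec = ap.parameter_recovery_report(truth, desk_fit_m2)
        shuffled = ap.CohortTruth(
            params=truth.params.assign(
                sigma_prior=np.random.default_rng(0).permutation(
                    truth.params["sigma_prior"].to_numpy())),
            participants=truth.participants, generative=truth.generative,
            task=truth.task)
        rec_shuffled = ap.parameter_recovery_report(shuffled, desk_fit_m2)
        assert rec["cells"]["sigma_prior"]["corr"] > 0.8
        assert abs(rec_shuffled["cells"]["sigma_prior"]["corr"]) < 0.3

    def test_posterior_predictive_calibration(self, desk_fit_m2):
        ppc = ap.posterior_predictive(desk_fit_m2, n_rep=200, seed=6)
        assert ppc["coverage"] == pytest.approx(0.95, abs=0.03)
        # per-condition coverages aggregate to the pooled value
        pooled = np.mean(list(ppc["coverage_by_condition"].values()))
        assert pooled == pytest.approx(ppc["coverage"], abs=0.02)

    def test_waic_self_comparison_is_null(self, desk_fit_m2):
        comp = ap.compare_waic([desk_fit_m2, desk_fit_m2])
        d = comp.table.set_index(["model_a", "model_b"])
        assert d.loc[("m2", "m2"), "delta_waic"].max() == 0.0
        assert d.loc[("m2", "m2"), "se_delta_waic"].max() == 0.0

    def test_mismatched_trial_sets_rejected(self, desk_fit_m2, small_cohort):
        _, trials = small_cohort
        other = ap.fit_hierarchical(trials, "m1", chains=2, samples=20,
                                    warmup=20, thin=1, seed=7)
        with pytest.raises(ValueError):
            ap.compare_waic([desk_fit_m2, other])


class TestExtraction:
    @pytest.mark.parametrize("sp, perf, expected",
                             [(10.0, 10.0, 0.5), (0.0, 5.0, 0.0),
                              (10.0, 20.0, 1 / 3)])
    def test_normalized_prior_sd(self, sp, perf, expected):
        assert ap.normalized_prior_sd(sp, perf) == pytest.approx(expected)

    def test_nonpositive_performance_sd_rejected(self):
        with pytest.raises(ValueError):
            ap.normalized_prior_sd(10.0, 0.0)

    def test_recovery_requires_matching_ids(self, desk_fit_m2):
        truth = ap.sample_cohort(5, seed=8)
        with pytest.raises(ValueError):
            ap.parameter_recovery_report(truth, desk_fit_m2)
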