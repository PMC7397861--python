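"""Synthetic-cohort generator: ground-truth structure, observer identity,
trait-link construction."""

import numpy as np
import pytest

import actionprior as ap
from actionprior.cohort import link_trait
from conftest import fixed_weight_generative, reduced_task


class TestSampleCohort:
    def test_cohort_shape(self):
        truth = ap.sample_cohort(47, seed=0)
        assert truth.participants.shape[0] == 47
        assert truth.params.shape[0] == 47 * 4
        assert truth.params.groupby("participant_id").size().eq(4).all()

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            ap.sample_cohort(1, seed=0)

    def test_reproducible(self):
        a = ap.sample_cohort(10, seed=5)
        b = ap.sample_cohort(10, seed=5)
        assert a.params.equals(b.params)
        assert a.participants.equals(b.participants)

    def test_default_population_structure(self):
        """Defaults put the group-mean weight near 0.7 and make prior SDs
        smaller than the corresponding performance spread for most cells."""
        truth = ap.sample_cohort(200, seed=1)
        w = truth.params.eval(
            "sigma_evidence**2 / (sigma_evidence**2 + sigma_prior**2)")
        assert 0.6 < w.mean() < 0.8
        # performance SD in px: force SD mapped through the local slope of
        # the force->position map at the nominal force
        cfg = truth.task
        for effort in ("low", "high"):
            sub = truth.params[truth.params["effort"] == effort]
            f = cfg.effort_fractions[effort]
            slope = (ap.force_to_position(f + 5e-4, effort, cfg)
                     - ap.force_to_position(f - 5e-4, effort, cfg)) / 1e-3
            perf_sd_px = sub["force_sd"] * slope
            assert (sub["sigma_prior"] < perf_sd_px).mean() > 0.8

    def test_ami_scores_in_range(self):
        truth = ap.sample_cohort(100, seed=2)
        for col in ("ami_behavioral_activation", "ami_emotional_sensitivity",
                    "ami_social_motivation", "ami_total"):
            assert truth.participants[col].between(0, 4).all()

    def test_truth_json_roundtrip(self, tmp_path):
        truth = ap.sample_cohort(5, seed=3)
        truth.to_json(tmp_path / "truth.json")
        back = ap.CohortTruth.from_json(tmp_path / "truth.json")
        assert np.allclose(back.params["sigma_prior"], truth.params["sigma_prior"])
        assert back.generative.trait_link_rho == truth.generative.trait_link_rho


class TestLinkTrait:
    def _partial_r(self, x, y, z):
        return ap.partial_correlation(x, y, z, bayes=False).r

    def test_invalid_rho_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            link_trait(rng.random(10), rng.random(10), rho=1.0)

    def test_null_link_gives_near_zero_partial_correlation(self):
        rng = np.random.default_rng(1)
        sp, sd = rng.lognormal(4, 0.4, 800), rng.lognormal(4.5, 0.3, 800)
        ami = link_trait(sp, sd, rho=0.0, seed=2)
        assert abs(self._partial_r(sp, ami["behavioral_activation"], sd)) < 0.08

    def test_target_rho_reached_at_large_n(self):
        rng = np.random.default_rng(3)
        sp, sd = rng.lognormal(4, 0.4, 500), rng.lognormal(4.5, 0.3, 500)
        ami = link_trait(sp, sd, rho=0.37, seed=4)
        assert self._partial_r(sp, ami["behavioral_activation"], sd) == \
            pytest.approx(0.37, abs=0.1)

    def test_near_deterministic_limit(self):
        rng = np.random.default_rng(5)
        sp, sd = rng.lognormal(4, 0.4, 300), rng.lognormal(4.5, 0.3, 300)
        ami = link_trait(sp, sd, rho=0.999, seed=6)
        assert self._partial_r(sp, ami["behavioral_activation"], sd) > 0.95


class TestSimulateTrials:
    def test_trial_invariants_hold_rowwise(self, small_cohort):
        _, trials = small_cohort
        basic = trials[trials["trial_type"] == "basic"]
        est = trials[trials["trial_type"] == "estimation"]
        np.testing.assert_allclose(trials["performance_error"],
                                   trials["x_true"] - trials["x_target"])
        assert basic["x_estimate"].isna().all()
        assert est["x_estimate"].notna().all()
        np.testing.assert_allclose(est["estimation_error"],
                                   est["x_estimate"] - est["x_true"])
        cfg = ap.TaskConfig()
        assert trials["x_true"].between(cfg.start_x_px, cfg.screen_width_px).all()

    def test_reproducible_per_seed(self, small_cohort):
        truth, trials = small_cohort
        again = ap.simulate_trials(truth, seed=4, task=reduced_task(2))
        assert trials.equals(again)

    def test_flat_prior_limit_estimates_unbiased(self):
        gen = fixed_weight_generative(w=1e-6, shift=0.0)
        truth = ap.sample_cohort(4, generative=gen, seed=7)
        trials = ap.simulate_trials(truth, seed=8, task=reduced_task(2))
        est = trials.dropna(subset=["estimation_error"])
        assert abs(est["estimation_error"].mean()) < \
            3 * est["estimation_error"].std() / np.sqrt(len(est))

    def test_dominant_prior_limit_pins_estimate_to_target(self):
        gen = fixed_weight_generative(w=1 - 1e-9, shift=0.0)
        truth = ap.sample_cohort(4, generative=gen, seed=9)
        trials = ap.simulate_trials(truth, seed=10, task=reduced_task(2))
        est = trials.dropna(subset=["x_estimate"])
        np.testing.assert_allclose(est["x_estimate"], est["x_target"], atol=1e-3)

    @pytest.mark.parametrize("w", [0.5, 0.7])
    def test_estimation_error_regression_identity(self, w):
        """E[estimation error | performance error] = -w * performance error
        + (1-w) * s, the regression identity the weighting analysis rests
        on."""
        shift = -12.0
        gen = fixed_weight_generative(w=w, shift=shift)
        truth = ap.sample_cohort(12, generative=gen, seed=20 + int(10 * w))
        trials = ap.simulate_trials(truth, seed=21, task=reduced_task(2))
        est = trials.dropna(subset=["estimation_error"])
        x = est["performance_error"].to_numpy()
        y = est["estimation_error"].to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        assert slope == pytest.approx(-w, abs=0.04)
        assert intercept == pytest.approx((1 - w) * shift, abs=4.0)
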