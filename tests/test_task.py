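"""Task geometry, physics, scheduling, calibration and reward."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import actionprior as ap
from actionprior.task import FORCE_SAMPLE_HZ, ForceTrace, iter_blocks


@pytest.fixture
def config():
    return ap.TaskConfig()


class TestSchedule:
    def test_full_schedule_counts(self, config):
        trials = ap.generate_schedule(config, seed=42)
        assert len(trials) == 1080
        assert sum(t.trial_type == "estimation" for t in trials) == 320

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_block_constraints(self, config, seed):
        trials = ap.generate_schedule(config, seed=seed)
        for block in iter_blocks(trials):
            types = [t.trial_type for t in block]
            assert types[:3] == ["basic"] * 3
            assert all(not (a == b == "estimation")
                       for a, b in zip(types, types[1:]))
            assert types.count("estimation") == config.estimation_per_block

    def test_condition_balance_invariant_to_seed(self, config):
        for seed in (5, 6):
            trials = ap.generate_schedule(config, seed=seed)
            counts = {}
            for block in iter_blocks(trials):
                counts[(block[0].effort, block[0].reward)] = \
                    counts.get((block[0].effort, block[0].reward), 0) + 1
            assert set(counts.values()) == {config.blocks_per_condition}

    def test_reproducible_and_seed_sensitive(self, config):
        a = ap.generate_schedule(config, seed=7)
        b = ap.generate_schedule(config, seed=7)
        c = ap.generate_schedule(config, seed=8)
        key = lambda ts: [(t.block, t.trial_type, t.effort, t.reward) for t in ts]
        assert key(a) == key(b)
        assert key(a) != key(c)

    def test_no_estimation_trials_degenerate(self):
        cfg = ap.TaskConfig(trials_per_block=19, basic_per_block=19,
                            estimation_per_block=0)
        trials = ap.generate_schedule(cfg, seed=0)
        assert all(t.trial_type == "basic" for t in trials)

    def test_unsatisfiable_schedule_raises(self):
        cfg = ap.TaskConfig(trials_per_block=27, basic_per_block=14,
                            estimation_per_block=13)
        with pytest.raises(ValueError):
            ap.generate_schedule(cfg, seed=0)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            ap.TaskConfig(basic_per_block=20)
        with pytest.raises(ValueError):
            ap.TaskConfig(n_blocks=39)


class TestForceMapping:
    def test_zero_force_stays_at_start(self, config):
        assert ap.force_to_position(0.0, "low", config) == config.start_x_px

    def test_nominal_forces_land_on_targets(self, config):
        assert ap.force_to_position(0.35, "low", config) == pytest.approx(512.0)
        assert ap.force_to_position(0.65, "high", config) == pytest.approx(896.0)

    @pytest.mark.parametrize("effort", ["low", "high"])
    def test_monotone_and_invertible(self, config, effort):
        f = np.linspace(0.01, 0.8, 200)
        pos = ap.force_to_position(f, effort, config)
        in_range = pos < config.screen_width_px
        assert np.all(np.diff(pos[in_range]) > 0)
        back = ap.position_to_force(pos[in_range], effort, config)
        np.testing.assert_allclose(back, f[in_range], rtol=1e-9)

    def test_negative_force_rejected(self, config):
        with pytest.raises(ValueError):
            ap.force_to_position(-0.1, "low", config)


class TestForceTraces:
    @staticmethod
    def trace(values, duration):
        return ForceTrace(samples=np.asarray(values, dtype=float),
                          duration_s=duration)

    def test_constant_trace_response(self):
        tr = self.trace([5.0] * 180, 3.0)
        assert ap.extract_force_response(tr, max_force=10.0) == pytest.approx(0.5)

    def test_window_isolation(self):
        samples = [0.0] * 120 + [8.0] * 60
        tr = self.trace(samples, 3.0)
        assert ap.extract_force_response(tr, max_force=8.0) == pytest.approx(1.0)

    def test_ramp_matches_windowed_mean(self):
        samples = np.linspace(0, 10, 180)
        tr = self.trace(samples, 3.0)
        expected = samples[120:150].mean() / 12.0
        assert ap.extract_force_response(tr, max_force=12.0) == pytest.approx(
            expected, rel=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            ap.extract_force_response(self.trace([1.0] * 120, 2.0), max_force=1.0)

    def test_calibration_takes_max_of_trace_means(self):
        traces = [self.trace([v] * 600, 10.0) for v in (8.0, 10.0, 9.0)]
        assert ap.calibrate_max_force(traces) == pytest.approx(10.0)

    def test_calibration_prefers_stable_window(self):
        rng = np.random.default_rng(0)
        noisy = np.abs(rng.normal(20, 5, 300))
        stable = np.full(300, 7.0)
        tr = self.trace(np.concatenate([noisy, stable]), 10.0)
        traces = [tr, self.trace([1.0] * 600, 10.0), self.trace([2.0] * 600, 10.0)]
        assert ap.calibrate_max_force(traces) == pytest.approx(7.0)

    def test_calibration_matches_bruteforce_scan(self):
        rng = np.random.default_rng(1)
        traces = [self.trace(np.abs(rng.normal(10, 3, 600)), 10.0) for _ in range(3)]
        w = 5 * FORCE_SAMPLE_HZ
        per_trace = []
        for tr in traces:
            best = min(range(len(tr.samples) - w + 1),
                       key=lambda i: np.var(tr.samples[i:i + w]))
            per_trace.append(np.mean(tr.samples[best:best + w]))
        assert ap.calibrate_max_force(traces) == pytest.approx(max(per_trace), rel=1e-12)

    def test_calibration_input_validation(self):
        good = self.trace([5.0] * 600, 10.0)
        with pytest.raises(ValueError):
            ap.calibrate_max_force([good, good])
        with pytest.raises(ValueError):
            ap.calibrate_max_force([good, good, self.trace([5.0] * 300, 5.0)])


class TestReward:
    def test_ramp_anchor_points(self, config):
        assert ap.reward_points(0.0, "low", config) == pytest.approx(1.0)
        assert ap.reward_points(192.0, "low", config) == pytest.approx(0.0)
        assert ap.reward_points(96.0, "low", config) == pytest.approx(0.5)
        assert ap.reward_points(-96.0, "low", config) == pytest.approx(0.5)

    @given(st.floats(min_value=-500, max_value=500),
           st.floats(min_value=0, max_value=100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_non_increasing_nonnegative_continuous(self, err, delta):
        cfg = ap.TaskConfig()
        r0 = ap.reward_points(abs(err), "high", cfg)
        r1 = ap.reward_points(abs(err) + delta, "high", cfg)
        assert 0.0 <= r1 <= r0 <= 1.0
        near = ap.reward_points(abs(err) + 1e-9, "high", cfg)
        assert abs(near - r0) < 1e-6
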