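import numpy as np
import pytest

from rewardremap.remapping import (
    RAD_PER_50CM,
    align_to_reward,
    bin_phase,
    classify_remapping,
    from_periodic,
    reward_align_tensor,
    rr_cell_criteria,
    rr_population_test,
    teleport_distance_control,
    to_periodic,
    trial_peak_errors,
    wrap_phase,
)


class TestPeriodicCoordinates:
    def test_track_start_maps_to_minus_pi(self):
        assert np.isclose(to_periodic(0.0), -np.pi)

    def test_fifty_cm_spans_0p698_radians(self):
        span = to_periodic(130.0) - to_periodic(80.0)
        assert np.isclose(span, 0.6981317, atol=1e-6)
        assert np.isclose(RAD_PER_50CM, 0.6981317, atol=1e-6)

    def test_roundtrip_identity(self, rng):
        pos = rng.uniform(0, 450, 200)
        back = from_periodic(to_periodic(pos))
        assert np.allclose(back, pos, atol=1e-9)

    def test_zone_start_aligns_to_zero(self):
        z = to_periodic(200.0)
        assert np.isclose(align_to_reward(z, z), 0.0)

    def test_reward_align_tensor_puts_zone_bin_first(self):
        v = np.zeros((2, 45))
        v[0, 20] = 1.0   # activity at bin 20, zone start bin 20
        v[1, 32] = 1.0   # zone start bin 32
        out = reward_align_tensor(v, np.array([20, 32]))
        assert out[0, 0] == 1.0 and out[1, 0] == 1.0


def _bump(center_bin, n_bins=45, sd=2.0):
    b = np.arange(n_bins)
    d = np.minimum(np.abs(b - center_bin), n_bins - np.abs(b - center_bin))
    return np.exp(-(d**2) / (2 * sd**2))


class TestClassifyRules:
    common = dict(zone_bin_before=8, zone_bin_after=20, n_bins=45)

    def test_stable_track_peak_is_tr(self):
        cat = classify_remapping(True, True, 10, 13, mean_post_dff=1.0,
                                 pre_trial_means=np.ones(20), **self.common)
        assert cat == "TR"

    def test_silent_after_with_sig_before_is_disappearing(self):
        cat = classify_remapping(True, False, 10, 10, mean_post_dff=0.0,
                                 pre_trial_means=np.ones(20), **self.common)
        assert cat == "disappearing"

    def test_activity_surge_with_sig_after_is_appearing(self):
        cat = classify_remapping(False, True, 10, 22, mean_post_dff=5.0,
                                 pre_trial_means=np.full(20, 0.5),
                                 **self.common)
        assert cat == "appearing"

    def test_peaks_near_both_zones_is_remap_near_reward(self):
        # pre peak at zone-before start (bin 8), post at zone-after (bin 20)
        cat = classify_remapping(True, True, 9, 21, mean_post_dff=1.0,
                                 pre_trial_means=np.ones(20), **self.common)
        assert cat == "remap_near_reward"

    def test_large_move_far_from_zone_is_remap_far(self):
        cat = classify_remapping(True, True, 2, 40, mean_post_dff=1.0,
                                 pre_trial_means=np.ones(20), **self.common)
        assert cat == "remap_far_from_reward"

    def test_nonsignificant_both_is_nonplace(self):
        cat = classify_remapping(False, False, 0, 0, mean_post_dff=0.0,
                                 pre_trial_means=np.zeros(20), **self.common)
        assert cat == "nonplace"


class TestRRCellCriteria:
    def test_identical_reward_aligned_tuning_passes_at_lag_zero(self, rng):
        curve = _bump(5)
        pre = np.tile(curve, (20, 1)) + rng.normal(0, 0.01, (20, 45))
        post = np.tile(curve, (20, 1)) + rng.normal(0, 0.01, (20, 45))
        res = rr_cell_criteria(pre, post, n_shuffles=200, rng=rng)
        assert res.is_rr
        assert abs(res.xcorr_lag_bins) <= 1
        assert abs(res.rel_peak_diff) < 0.2

    def test_ten_bin_shift_fails_the_lag_rule(self, rng):
        pre = np.tile(_bump(5), (20, 1)) + rng.normal(0, 0.01, (20, 45))
        post = np.tile(_bump(15), (20, 1)) + rng.normal(0, 0.01, (20, 45))
        res = rr_cell_criteria(pre, post, n_shuffles=200, rng=rng)
        assert not res.is_rr
        assert abs(res.xcorr_lag_bins) > 5 or not res.peak_within

    def test_flat_tuning_fails_without_error(self, rng):
        pre = np.full((20, 45), 1.0)
        post = np.full((20, 45), 1.0)
        res = rr_cell_criteria(pre, post, n_shuffles=100, rng=rng)
        assert not res.is_rr


class TestRRPopulationTest:
    def _population(self, rng, n_rr=40, n_rand=0, n_trials=30):
        """trials x bins x neurons tensor: RR cells + random remappers."""
        zb1, zb2 = 8, 20
        n = n_rr + n_rand
        pre = np.empty((n_trials, 45, n))
        post = np.empty((n_trials, 45, n))
        anchors = rng.integers(0, 45, n)
        for i in range(n):
            pre[:, :, i] = _bump((anchors[i] + zb1) % 45)
            if i < n_rr:
                post[:, :, i] = _bump((anchors[i] + zb2) % 45)
            else:
                post[:, :, i] = _bump(rng.integers(0, 45))
        vals = np.concatenate([pre, post], axis=0)
        zone_bins = np.array([zb1] * n_trials + [zb2] * n_trials)
        trials = np.arange(2 * n_trials)
        return vals, zone_bins, trials[:n_trials], trials[n_trials:]

    def test_perfect_rr_population_is_a_spike_at_zero(self, rng):
        vals, zb, pre, post = self._population(rng, n_rr=40)
        sig = np.ones(40, dtype=bool)
        res = rr_population_test(vals, zb, pre, post, sig, sig, n_place=40,
                                 n_shuffles=200, rng=rng)
        assert np.all(np.abs(res.diffs) <= RAD_PER_50CM)
        assert res.significant
        # nearly the whole population sits above the shuffle expectation
        assert res.above_chance_fraction > 0.5

    def test_random_remapping_population_is_near_chance(self):
        rng = np.random.default_rng(42)
        vals, zb, pre, post = self._population(rng, n_rr=0, n_rand=300)
        sig = np.ones(300, dtype=bool)
        res = rr_population_test(vals, zb, pre, post, sig, sig, n_place=300,
                                 n_shuffles=300, rng=rng)
        assert abs(res.above_chance_fraction) < 0.07

    def test_growing_exclusion_radius_shrinks_eligibility(self, rng):
        vals, zb, pre, post = self._population(rng, n_rr=40)
        sig = np.ones(40, dtype=bool)
        counts = []
        for radius in (0.0, 60.0, 120.0, 225.0):
            res = rr_population_test(vals, zb, pre, post, sig, sig,
                                     n_place=40, n_shuffles=50, rng=rng,
                                     exclusion_radius_cm=radius)
            counts.append(res.n_eligible)
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0

    def test_low_n_flag(self, rng):
        vals, zb, pre, post = self._population(rng, n_rr=5)
        sig = np.ones(5, dtype=bool)
        res = rr_population_test(vals, zb, pre, post, sig, sig, n_place=5,
                                 n_shuffles=50, rng=rng)
        assert res.low_n


class TestTeleportControl:
    def test_distance_anchored_cell_correlates(self, rng):
        dist = rng.uniform(50, 400, 60)
        err = 0.2 * dist + rng.normal(0, 5, 60)
        rho, p = teleport_distance_control(err, dist)
        assert rho > 0.5 and p < 0.01

    def test_reward_anchored_cell_does_not(self, rng):
        dist = rng.uniform(50, 400, 60)
        err = rng.normal(0, 10, 60)
        rho, p = teleport_distance_control(err, dist)
        assert abs(rho) < 0.35

    def test_constant_error_is_nan(self):
        rho, p = teleport_distance_control(np.full(30, 2.0),
                                           np.linspace(10, 100, 30))
        assert np.isnan(rho)

    def test_trial_peak_errors_zero_for_stable_cell(self):
        m = np.tile(_bump(12), (10, 1))
        err = trial_peak_errors(m, np.arange(10))
        np.testing.assert_allclose(err, 0.0, atol=1e-9)
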