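import numpy as np
import pytest

from rewardremap.signals import (
    bin_by_position,
    compute_dff,
    correlation_matrix,
    exclude_putative_interneurons,
)


def _brute_maximin(f, w):
    """Centered rolling min then rolling max with window truncation
    (pandas convention: window [i - w//2, i + (w-1)//2])."""
    n = len(f)

    def roll(x, op):
        out = np.empty(n)
        for i in range(n):
            lo = max(0, i - w // 2)
            hi = min(n, i + (w - 1) // 2 + 1)
            out[i] = op(x[lo:hi])
        return out

    return roll(roll(f, np.min), np.max)


class TestComputeDff:
    def test_constant_trace_gives_zero(self):
        f = np.full(100, 3.0)
        trials = np.repeat([0, 1], 50)
        dff, flagged = compute_dff(f, trials, frame_rate_hz=10.0)
        np.testing.assert_allclose(dff, 0.0, atol=1e-12)
        assert not flagged.any()

    def test_step_matches_hand_computed_maximin(self):
        # 30-sample toy at 1 Hz with a brief step: oracle by explicit loops
        f = np.ones(30)
        f[10:15] = 2.0
        trials = np.zeros(30, dtype=int)
        dff, _ = compute_dff(f, trials, frame_rate_hz=1.0, window_s=9,
                             smooth_sd_samples=0)
        base = _brute_maximin(f, 9)
        np.testing.assert_allclose(dff, (f - base) / np.abs(base))
        # transient is positive and returns toward 0 after the step
        assert dff[12] > 0
        assert abs(dff[29]) < 1e-12

    def test_baselines_are_independent_across_trials(self):
        f = np.concatenate([np.full(40, 1.0), np.full(40, 10.0)])
        trials = np.repeat([0, 1], 40)
        dff, _ = compute_dff(f, trials, frame_rate_hz=2.0)
        np.testing.assert_allclose(dff, 0.0, atol=1e-12)

    def test_zero_baseline_is_guarded_and_flagged(self):
        f = np.zeros(20)
        trials = np.zeros(20, dtype=int)
        dff, flagged = compute_dff(f, trials, frame_rate_hz=2.0)
        assert np.isfinite(dff).all()
        assert flagged.all()


class TestBinByPosition:
    edges = np.arange(0.0, 31.0, 10.0)  # 3 bins on a 30-cm toy track

    def test_toy_case_matches_brute_force_average(self):
        pos = np.array([2.0, 5.0, 14.0, 25.0, 3.0, 16.0, 17.0, 28.0])
        trace = np.array([1.0, 3.0, 5.0, 7.0, 2.0, 4.0, 6.0, 8.0])
        speed = np.full(8, 10.0)
        trials = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        m = bin_by_position(trace, pos, speed, trials, self.edges)
        expected = np.array([[2.0, 5.0, 7.0], [2.0, 5.0, 8.0]])
        np.testing.assert_allclose(m.values, expected)

    def test_constant_trace_full_occupancy(self):
        pos = np.array([1.0, 11.0, 21.0])
        m = bin_by_position(np.full(3, 4.2), pos, np.full(3, 5.0),
                            np.zeros(3, dtype=int), self.edges)
        np.testing.assert_allclose(m.values, 4.2)

    def test_slow_frames_are_excluded(self):
        pos = np.array([1.0, 11.0, 21.0])
        m = bin_by_position(np.ones(3), pos, np.full(3, 1.0),
                            np.zeros(3, dtype=int), self.edges)
        assert np.isnan(m.values).all()

    def test_empty_bin_is_nan_not_zero(self):
        pos = np.array([1.0, 21.0])
        m = bin_by_position(np.ones(2), pos, np.full(2, 5.0),
                            np.zeros(2, dtype=int), self.edges)
        assert np.isnan(m.values[0, 1])

    def test_track_end_wraps_to_bin_zero(self):
        m = bin_by_position(np.array([9.0]), np.array([30.0]),
                            np.array([5.0]), np.array([0]), self.edges)
        assert m.values[0, 0] == 9.0

    def test_invariant_to_frame_upsampling(self):
        pos = np.array([2.0, 14.0, 25.0, 8.0])
        trace = np.array([1.0, 5.0, 7.0, 3.0])
        speed = np.full(4, 10.0)
        trials = np.array([0, 0, 0, 0])
        m1 = bin_by_position(trace, pos, speed, trials, self.edges)
        rep = np.repeat
        m2 = bin_by_position(rep(trace, 3), rep(pos, 3), rep(speed, 3),
                             rep(trials, 3), self.edges)
        np.testing.assert_allclose(m1.values, m2.values)


class TestCorrelationMatrix:
    def test_identical_trials_correlate_perfectly(self):
        row = np.array([0.0, 1.0, 3.0, 1.0, 0.0])
        C = correlation_matrix(np.tile(row, (4, 1)), smooth_sd_cm=0)
        np.testing.assert_allclose(C, 1.0)

    def test_sign_flipped_profiles_anticorrelate(self):
        row = np.array([0.0, 1.0, 3.0, 1.0, 0.0])
        C = correlation_matrix(np.stack([row, -row]), smooth_sd_cm=0)
        assert np.isclose(C[0, 1], -1.0)

    def test_matches_pairwise_pearson_oracle(self, rng):
        A = rng.random((4, 12))
        C = correlation_matrix(A, smooth_sd_cm=0)
        np.testing.assert_allclose(C, np.corrcoef(A), atol=1e-12)

    def test_population_tensor_matches_concatenated_oracle(self, rng):
        A = rng.random((5, 8, 3))
        C = correlation_matrix(A, smooth_sd_cm=0)
        np.testing.assert_allclose(C, np.corrcoef(A.reshape(5, -1)), atol=1e-12)

    def test_symmetry_and_trial_permutation(self, rng):
        A = rng.random((6, 10))
        C = correlation_matrix(A, smooth_sd_cm=0)
        np.testing.assert_allclose(C, C.T)
        perm = rng.permutation(6)
        Cp = correlation_matrix(A[perm], smooth_sd_cm=0)
        np.testing.assert_allclose(Cp, C[np.ix_(perm, perm)], atol=1e-12)

    def test_zero_variance_trial_yields_nan(self):
        A = np.vstack([np.ones(6), np.arange(6.0), np.arange(6.0)[::-1]])
        C = correlation_matrix(A, smooth_sd_cm=0)
        assert np.isnan(C[0]).all() and np.isnan(C[:, 0]).all()
        assert np.isclose(C[1, 2], -1.0)

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            correlation_matrix(np.ones((1, 5)), smooth_sd_cm=0)


class TestInterneuronExclusion:
    def test_speed_trace_itself_is_excluded(self, rng):
        speed = rng.random(500) * 30
        keep, r = exclude_putative_interneurons(speed[None, :], speed)
        assert not keep[0]
        assert np.isclose(r[0], 1.0)

    def test_noise_trace_is_kept(self, rng):
        speed = rng.random(500) * 30
        keep, _ = exclude_putative_interneurons(
            rng.standard_normal((1, 500)), speed)
        assert keep[0]

    def test_moderate_correlation_below_threshold_is_kept(self, rng):
        speed = rng.random(2000) * 30
        noise = rng.standard_normal(2000) * speed.std() * 2.3
        trace = speed + noise
        r_direct = np.corrcoef(trace, speed)[0, 1]
        assert 0.2 < r_direct < 0.5  # construction sanity
        keep, r = exclude_putative_interneurons(trace[None, :], speed)
        assert keep[0]
        assert np.isclose(r[0], r_direct)

    def test_constant_trace_kept_with_nan_r(self):
        keep, r = exclude_putative_interneurons(
            np.ones((1, 100)), np.arange(100.0))
        assert keep[0] and np.isnan(r[0])
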