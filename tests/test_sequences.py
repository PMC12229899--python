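from itertools import permutations

import numpy as np
import pytest

from rewardremap.sequences import (
    circ_circ_corr,
    circular_variance,
    cross_validated_sequence,
    iou,
    match_rois_across_days,
    recruitment_table,
    sequence_density,
    sequence_permutation_test,
)


class TestCircCircCorr:
    def test_identity_gives_one(self, rng):
        a = rng.uniform(-np.pi, np.pi, 30)
        assert np.isclose(circ_circ_corr(a, a), 1.0)

    def test_reflection_gives_minus_one(self, rng):
        a = rng.uniform(-np.pi, np.pi, 30)
        assert np.isclose(circ_circ_corr(a, -a), -1.0)

    def test_matches_pingouin_estimator(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(5):
            a = rng.uniform(-np.pi, np.pi, 20)
            b = rng.uniform(-np.pi, np.pi, 20)
            r_ref, _ = pingouin.circ_corrcc(a, b)
            assert np.isclose(circ_circ_corr(a, b), r_ref, atol=1e-10)

    def test_invariant_to_constant_phase_offsets(self, rng):
        a = rng.uniform(-np.pi, np.pi, 25)
        b = a + rng.normal(0, 0.3, 25)
        r0 = circ_circ_corr(a, b)
        r1 = circ_circ_corr(a + 1.1, b)
        r2 = circ_circ_corr(a, b - 2.3)
        r3 = circ_circ_corr(a + 0.7, b + 0.7)
        assert np.allclose([r1, r2, r3], r0, atol=1e-9)

    def test_degenerate_identical_phases_is_nan(self):
        assert np.isnan(circ_circ_corr(np.zeros(10), np.ones(10)))


class TestPermutationTest:
    def test_p_floor_when_observed_beats_all_shuffles(self, rng):
        a = np.sort(rng.uniform(-np.pi, np.pi, 40))
        rho, p = sequence_permutation_test(a, a, n_perm=1000, rng=rng)
        assert np.isclose(rho, 1.0)
        assert np.isclose(p, 1 / 1001)
        assert p < 0.001

    def test_exhaustive_three_cell_enumeration_matches_brute_force(self, rng):
        a = np.array([0.3, 1.2, -2.0])
        b = np.array([0.5, 1.0, -1.8])
        rho, p = sequence_permutation_test(a, b, exhaustive=True)
        shufs = [abs(circ_circ_corr(a, b[list(q)]))
                 for q in permutations(range(3))]
        expect = np.mean(np.array(shufs) >= abs(rho))
        assert np.isclose(p, expect)

    def test_null_p_values_are_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(40):
            a = rng.uniform(-np.pi, np.pi, 15)
            b = rng.uniform(-np.pi, np.pi, 15)
            ps.append(sequence_permutation_test(a, b, n_perm=99, rng=rng)[1])
        assert 0.2 < np.mean(ps) < 0.8


class TestCrossValidatedSequence:
    def test_noiseless_sequence_positions_match_anchors(self):
        n_cells, n_trials = 10, 20
        v = np.zeros((n_trials, 45, n_cells))
        anchors = np.linspace(2, 42, n_cells).astype(int)
        for i, a in enumerate(anchors):
            v[:, a, i] = 1.0
        res = cross_validated_sequence(v, np.arange(10), np.arange(10, 20))
        order = np.argsort(anchors, kind="stable")
        np.testing.assert_array_equal(res.sort_order, order)
        assert np.isclose(res.rho, 1.0)
        assert res.p_perm < 0.01

    def test_rr_population_keeps_order_in_reward_space(self, small_session):
        from rewardremap.remapping import reward_align_tensor
        from rewardremap.signals import bin_session
        s, gt = small_session
        pre, post = s.trial_sets()
        tensor = bin_session(s, "dff")
        bw = s.track_length_cm / s.n_bins
        zb = (s.trials["zone_start_cm"].to_numpy() / bw).round().astype(int)
        rr_vals = reward_align_tensor(tensor.values, zb)
        cells = gt.neurons_of_class("RR")
        res = cross_validated_sequence(rr_vals, pre, post, cells=cells,
                                       n_perm=500, rng=np.random.default_rng(3))
        assert res.rho > 0.5
        assert res.p_perm < 0.01

    def test_fewer_than_five_cells_is_flagged(self, rng):
        v = rng.random((10, 45, 3))
        res = cross_validated_sequence(v, np.arange(5), np.arange(5, 10))
        assert res.low_n and np.isnan(res.rho)


class TestDensityAndVariance:
    def test_single_bin_spike(self):
        ph = np.full(20, 0.5)
        d = sequence_density(ph, n_place_cells=40)
        assert d.sum() == 0.5 and (d > 0).sum() == 1
        assert circular_variance(ph) == 0.0

    def test_uniform_phases_high_variance(self):
        ph = np.linspace(-np.pi, np.pi, 721)[:-1]
        assert circular_variance(ph) > 0.999

    def test_von_mises_variance_matches_closed_form(self):
        from scipy.special import iv
        rng = np.random.default_rng(11)
        kappa = 2.0
        ph = rng.vonmises(0.0, kappa, 4000)
        expect = 1 - iv(1, kappa) / iv(0, kappa)
        assert abs(circular_variance(ph) - expect) < 0.02


class TestRoiMatching:
    def _mask(self, pixels, shape=(8, 8)):
        m = np.zeros(shape, dtype=bool)
        for r, c in pixels:
            m[r, c] = True
        return m

    def test_identical_masks_match_with_iou_one(self):
        m = self._mask([(1, 1), (1, 2), (2, 1)])
        out = match_rois_across_days([m], [m.copy()])
        assert len(out) == 1 and out["iou"].iloc[0] == 1.0

    def test_disjoint_masks_do_not_match(self):
        a = self._mask([(0, 0)])
        b = self._mask([(5, 5)])
        assert len(match_rois_across_days([a], [b])) == 0

    def test_three_mask_toy_matches_hand_computed_ious(self):
        a1 = self._mask([(0, 0), (0, 1), (1, 0), (1, 1)])   # 4 px
        a2 = self._mask([(4, 4), (4, 5)])                   # 2 px
        b1 = self._mask([(0, 0), (0, 1), (1, 0)])           # IoU(a1,b1)=3/4
        b2 = self._mask([(4, 5), (4, 6)])                   # IoU(a2,b2)=1/3
        assert np.isclose(iou(a1, b1), 0.75)
        assert np.isclose(iou(a2, b2), 1 / 3)
        out = match_rois_across_days([a1, a2], [b1, b2])
        assert set(zip(out["roi_day1"], out["roi_day2"])) == {(0, 0), (1, 1)}

    def test_empty_masks_are_excluded(self):
        a = self._mask([(0, 0)])
        empty = np.zeros((8, 8), dtype=bool)
        out = match_rois_across_days([a, empty], [a.copy()])
        assert out["roi_day1"].tolist() == [0]


class TestRecruitment:
    def test_identical_labels_give_diagonal_ones(self):
        import pandas as pd
        labels = ["RR", "TR", "RR", "nonplace"]
        matching = pd.DataFrame(dict(roi_day1=range(4), roi_day2=range(4),
                                     iou=[1.0] * 4))
        out = recruitment_table(labels, labels, matching)
        same = out[out["from_label"] == out["to_label"]]
        assert (same["fraction"] == 1.0).all()

    def test_simulated_retention_rate_is_recovered(self):
        import pandas as pd
        rng = np.random.default_rng(8)
        n = 400
        day_a = ["RR"] * n
        stay = rng.random(n) < 0.3
        day_b = np.where(stay, "RR", "TR")
        matching = pd.DataFrame(dict(roi_day1=range(n), roi_day2=range(n),
                                     iou=[1.0] * n))
        out = recruitment_table(day_a, day_b, matching)
        rr_rr = out[(out["from_label"] == "RR") & (out["to_label"] == "RR")]
        assert abs(rr_rr["fraction"].iloc[0] - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_no_matches_gives_empty_table(self):
        import pandas as pd
        out = recruitment_table(["RR"], ["RR"],
                                pd.DataFrame(columns=["roi_day1", "roi_day2",
                                                      "iou"]))
        assert len(out) == 0


class TestCircularMeanCI:
    def test_concentrated_sample_ci_brackets_the_true_direction(self):
        from rewardremap.sequences import bootstrap_circular_mean_ci
        rng = np.random.default_rng(2)
        ph = rng.vonmises(0.8, 8.0, 200)
        m, lo, hi = bootstrap_circular_mean_ci(ph, n_boot=2000, rng=3)
        assert lo <= 0.8 <= hi
        assert lo <= m <= hi
        assert not (lo <= 0.0 <= hi)   # bias away from 0 is resolved

    def test_empty_sample_is_nan(self):
        from rewardremap.sequences import bootstrap_circular_mean_ci
        m, lo, hi = bootstrap_circular_mean_ci([], n_boot=10)
        assert np.isnan(m)
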