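from itertools import product

import numpy as np
import pytest

from rewardremap.switchtime import (
    silhouette_by_k,
    distance_score,
    factorized_kmeans,
    fit_remap_sigmoid,
    kmeans_significance,
    lag_table,
    normalize_01,
    remap_trial_pipeline,
)


def _two_map_tensor(n_pre=15, n_post=15, n_bins=20, n_neurons=6, noise=0.0,
                    rng=None):
    map1 = np.zeros((n_bins, n_neurons))
    map2 = np.zeros((n_bins, n_neurons))
    for i in range(n_neurons):
        map1[(2 * i) % n_bins, i] = 1.0
        map2[(2 * i + 7) % n_bins, i] = 1.0
    X = np.concatenate([np.tile(map1, (n_pre, 1, 1)),
                        np.tile(map2, (n_post, 1, 1))])
    if noise > 0:
        X = X + rng.normal(0, noise, X.shape)
    return X, map1, map2


class TestNormalize01:
    def test_constant_neuron_maps_to_zero_and_is_flagged(self):
        v = np.full((4, 5, 2), 3.0)
        v[:, :, 1] = np.arange(20).reshape(4, 5)
        out, const = normalize_01(v)
        assert const[0] and not const[1]
        assert (out[:, :, 0] == 0).all()
        assert out[:, :, 1].min() == 0.0 and out[:, :, 1].max() == 1.0

    def test_already_unit_range_is_unchanged(self, rng):
        v = rng.random((4, 5, 1))
        v[0, 0, 0], v[-1, -1, 0] = 0.0, 1.0
        out, _ = normalize_01(v)
        np.testing.assert_allclose(out, v)

    def test_toy_hand_check(self):
        v = np.array([[[2.0], [4.0]], [[6.0], [10.0]]])
        out, _ = normalize_01(v)
        np.testing.assert_allclose(out[:, :, 0], [[0.0, 0.25], [0.5, 1.0]])


class TestFactorizedKmeans:
    def test_two_repeated_maps_are_perfectly_separated(self):
        X, map1, map2 = _two_map_tensor()
        model = factorized_kmeans(X, restarts=10, rng=0)
        assert (model.labels[:15] == 0).all()
        assert (model.labels[15:] == 1).all()
        np.testing.assert_allclose(model.V[0], map1, atol=1e-12)
        np.testing.assert_allclose(model.V[1], map2, atol=1e-12)
        assert model.objective < 1e-12

    def test_first_cluster_is_the_first_seen_in_session(self, rng):
        X, _, _ = _two_map_tensor(noise=0.05, rng=rng)
        for seed in range(5):
            model = factorized_kmeans(X, restarts=5, rng=seed)
            assert model.labels[0] == 0

    def test_objective_matches_exhaustive_labeling_on_six_trials(self, rng):
        X = rng.random((6, 4, 1))
        model = factorized_kmeans(X, k=2, restarts=60, rng=1)
        flat = X.reshape(6, -1)
        best = np.inf
        for labels in product([0, 1], repeat=6):
            labels = np.array(labels)
            if labels.min() == labels.max():
                continue
            sse = 0.0
            for j in (0, 1):
                sel = flat[labels == j]
                sse += ((sel - sel.mean(axis=0)) ** 2).sum()
            best = min(best, sse)
        assert np.isclose(model.objective, best, atol=1e-10)

    def test_more_restarts_never_worsen_the_objective(self, rng):
        X = rng.random((20, 10, 2))
        o1 = factorized_kmeans(X, restarts=1, rng=3).objective
        o100 = factorized_kmeans(X, restarts=100, rng=3).objective
        assert o100 <= o1

    def test_k_above_trial_count_raises(self):
        with pytest.raises(ValueError):
            factorized_kmeans(np.ones((3, 4, 1)), k=5)


class TestSignificance:
    def test_strong_two_map_session_is_included(self, rng):
        X, _, _ = _two_map_tensor(noise=0.1, rng=rng)
        include, p, real, null = kmeans_significance(X, reps=20, restarts=5,
                                                     rng=0)
        assert include and p < 0.05
        assert real.mean() > null.mean()

    def test_structureless_session_is_excluded(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (30, 10, 3))
        include, p, _, _ = kmeans_significance(X, reps=20, restarts=5, rng=1)
        assert not include

    def test_zero_holdout_rejected(self):
        with pytest.raises(ValueError):
            kmeans_significance(np.ones((10, 4, 1)), holdout=0.0)


class TestDistanceScore:
    def test_centroids_map_to_plus_minus_one_and_midpoint_to_zero(self, rng):
        V1 = rng.random((8, 3))
        V2 = rng.random((8, 3))
        X = np.stack([V1, V2, (V1 + V2) / 2])
        P = distance_score(X, V1, V2)
        np.testing.assert_allclose(P, [-1.0, 1.0, 0.0], atol=1e-12)

    def test_invariant_to_consistent_rotation_of_features(self, rng):
        V1 = rng.random(12)
        V2 = rng.random(12)
        X = rng.random((6, 12, 1))
        Q, _ = np.linalg.qr(rng.standard_normal((12, 12)))
        P0 = distance_score(X, V1, V2)
        P1 = distance_score(X.reshape(6, 12) @ Q, V1 @ Q, V2 @ Q)
        np.testing.assert_allclose(P0, P1, atol=1e-10)

    def test_identical_centroids_give_nan(self):
        V = np.ones((4, 2))
        P = distance_score(np.ones((3, 4, 2)), V, V)
        assert np.isnan(P).all()


class TestRemapSigmoid:
    def test_ideal_step_at_trial_30_has_inflection_near_29p5(self):
        P = np.concatenate([np.full(30, -1.0), np.full(30, 1.0)])
        res = fit_remap_sigmoid(P)
        assert res.converged
        assert abs(res.remap_trial - 29.5) <= 0.5

    def test_noiseless_logistic_recovers_its_own_inflection(self):
        t = np.arange(50, dtype=float)
        P = -0.8 + 1.6 / (1 + np.exp(-1.3 * (t - 21.7)))
        res = fit_remap_sigmoid(P)
        assert res.converged
        assert abs(res.remap_trial - 21.7) < 0.05
        assert abs(res.params["slope"] - 1.3) < 0.05

    def test_flat_series_is_not_converged(self):
        res = fit_remap_sigmoid(np.zeros(40))
        assert not res.converged and np.isnan(res.remap_trial)

    def test_pipeline_recovers_switch_trial_on_two_map_data(self, rng):
        X, _, _ = _two_map_tensor(n_pre=20, n_post=20, noise=0.05, rng=rng)
        series, model = remap_trial_pipeline(X, restarts=20, rng=0)
        assert series.converged
        assert abs(series.remap_trial - 19.5) <= 1.0


class TestLagTable:
    def test_identical_remap_trials_give_zero_lags(self):
        out = lag_table(dict(neural_PV=30.0, licking=30.0, speed=30.0))
        assert out["neural_lead_over_lick"].iloc[0] == 0.0
        assert out["neural_lead_over_speed"].iloc[0] == 0.0

    def test_neural_lead_is_positive_when_neural_remaps_first(self):
        out = lag_table(dict(neural_PV=29.5, licking=31.5, speed=30.5))
        assert out["neural_lead_over_lick"].iloc[0] == 2.0

    def test_missing_domain_excludes_the_session(self):
        out = lag_table(dict(neural_PV=30.0, licking=np.nan, speed=30.0))
        assert len(out) == 0


class TestSilhouette:
    def test_two_map_session_prefers_k_equals_two(self, rng):
        X, _, _ = _two_map_tensor(noise=0.05, rng=rng)
        scores = silhouette_by_k(X, ks=(2, 3, 4), restarts=10, rng=0)
        assert scores[2] == max(scores.values())
        assert scores[2] > 0.5
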