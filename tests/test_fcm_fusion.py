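"""Fuzzy c-means clustering, cluster designation and majority fusion."""

import numpy as np
import pytest

from necromap.fcm_fusion import (WeightVector, assign_necrosis_cluster,
                                 designate_by_sign, fcm_cluster,
                                 necrosis_percentage, standardize_features,
                                 weighted_majority)


def _blobs(rng, n=50, sep=10.0, sd=0.1):
    X = np.concatenate([rng.normal(0, sd, n), rng.normal(sep, sd, n)])
    labels = np.concatenate([np.zeros(n, bool), np.ones(n, bool)])
    return X[:, None], labels


class TestFCM:
    def test_separated_blobs_recovered(self, rng):
        X, labels = _blobs(rng)
        res = fcm_cluster(X, seed=3)
        hard = res.U[:, 0] > 0.5
        acc = max((hard == labels).mean(), (hard != labels).mean())
        assert acc >= 0.99

    def test_membership_rows_sum_to_one(self, rng):
        X = rng.normal(size=(80, 5))
        res = fcm_cluster(X, seed=0)
        assert np.allclose(res.U.sum(axis=1), 1.0, atol=1e-12)

    def test_objective_nonincreasing_many_datasets(self, rng):
        for ds in range(10):
            X = rng.normal(size=(60, 3)) * rng.uniform(0.5, 3)
            for seed in range(3):
                res = fcm_cluster(X, seed=seed, n_restarts=1)
                assert np.all(np.diff(res.objective_trace) <= 1e-8)

    def test_single_repeated_point(self):
        X = np.tile([[2.0, -1.0]], (10, 1))
        res = fcm_cluster(X, seed=1)
        assert np.allclose(res.V, [[2.0, -1.0], [2.0, -1.0]])
        assert np.allclose(res.U, 0.5)

    def test_point_on_center_gets_crisp_membership(self, rng):
        X, _ = _blobs(rng)
        res = fcm_cluster(X, seed=2)
        # the pixel closest to a center should have near-crisp membership
        d = np.abs(X - res.V[0, 0])
        assert res.U[np.argmin(d), 0] > 0.99

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fcm_cluster(np.empty((0, 2)))

    def test_converges_before_max_iter(self, rng):
        X, _ = _blobs(rng)
        res = fcm_cluster(X, seed=0, max_iter=300)
        assert res.iterations < 300
        assert res.final_center_shift < 1e-5


class TestDesignation:
    def test_labels_matching_cluster_one(self, rng):
        X, labels = _blobs(rng)
        res = fcm_cluster(X, seed=1)
        mp = assign_necrosis_cluster(res, labels=labels)
        assert mp.agreement >= 0.99
        hard = mp.u > 0.5
        assert (hard == labels).mean() >= 0.99

    def test_inverted_labels_flip_designation(self, rng):
        X, labels = _blobs(rng)
        res = fcm_cluster(X, seed=1)
        a = assign_necrosis_cluster(res, labels=labels)
        b = assign_necrosis_cluster(res, labels=~labels)
        assert a.necrosis_cluster != b.necrosis_cluster
        assert np.allclose(a.u + b.u, 1.0)

    def test_agreement_tie_requires_adc(self):
        U = np.array([[0.9, 0.1], [0.1, 0.9]])
        V = np.array([[1.0], [0.0]])
        from necromap.fcm_fusion import FCMResult
        res = FCMResult(U=U, V=V, objective=0, objective_trace=np.zeros(1),
                        iterations=1, final_center_shift=0)
        # hard assignment is [True, False]; labels [True, True] agree
        # 50/50 with either designation -> tie needs an ADC tiebreak
        with pytest.raises(ValueError):
            assign_necrosis_cluster(res, labels=np.array([True, True]))
        mp = assign_necrosis_cluster(res, labels=np.array([True, True]),
                                     mean_adc_feature=[1.0, 0.0])
        assert mp.necrosis_cluster == 0

    def test_sign_consensus_designation(self, rng):
        X, labels = _blobs(rng, sep=8.0)
        res = fcm_cluster(X, seed=4)
        # consensus: necrosis has the higher value on feature 0
        mp = designate_by_sign(res, [0], [1.0])
        hard = mp.u > 0.5
        assert (hard == labels).mean() >= 0.99  # labels are the high blob

    def test_train_infer_consistency(self, rng):
        X, labels = _blobs(rng, sep=8.0)
        res = fcm_cluster(X, seed=5)
        trained = assign_necrosis_cluster(res, labels=labels)
        sign = np.sign(res.V[trained.necrosis_cluster]
                       - res.V[1 - trained.necrosis_cluster])
        inferred = designate_by_sign(res, [0], sign)
        assert inferred.necrosis_cluster == trained.necrosis_cluster


class TestWeightedMajority:
    def test_single_map_reduces_to_threshold(self):
        u = np.array([0.2, 0.51, 0.5])
        out = weighted_majority([u], WeightVector([1.0]))
        assert list(out.y) == [False, True, False]  # tie -> viable

    def test_unanimous_maps(self):
        ones = np.ones(4)
        w = WeightVector([0.5, 0.5])
        assert weighted_majority([ones, ones], w).y.all()
        assert not weighted_majority([0 * ones, 0 * ones], w).y.any()

    def test_hand_example_two_of_three(self):
        u = [np.array([0.9]), np.array([0.9]), np.array([0.0])]
        w = WeightVector([1 / 3, 1 / 3, 1 / 3])
        assert weighted_majority(u, w).y[0]  # 0.6 > 0.5 -> necrotic

    def test_uniform_weights_equal_vote_count_on_binary_maps(self, rng):
        maps = [rng.integers(0, 2, 30).astype(float) for _ in range(5)]
        w = WeightVector(np.full(5, 0.2))
        fused = weighted_majority(maps, w)
        votes = np.stack(maps).sum(axis=0)
        assert np.array_equal(fused.y, votes > 2.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_majority([np.zeros(3)], WeightVector([0.5, 0.5]))

    def test_weights_must_be_simplex(self):
        with pytest.raises(ValueError):
            WeightVector([0.5, 0.6])
        with pytest.raises(ValueError):
            WeightVector([-0.1, 1.1])


class TestNecrosisPercentage:
    def test_extremes_and_counts(self):
        from necromap.fcm_fusion import BinaryViabilityMap
        assert necrosis_percentage(
            BinaryViabilityMap(np.ones(10))) == 100.0
        assert necrosis_percentage(
            BinaryViabilityMap(np.zeros(10))) == 0.0
        y = np.zeros(100)
        y[:37] = 1
        assert necrosis_percentage(BinaryViabilityMap(y)) == 37.0

    def test_empty_map_rejected(self):
        from necromap.fcm_fusion import BinaryViabilityMap
        with pytest.raises(ValueError):
            necrosis_percentage(BinaryViabilityMap(np.zeros(0)))


class TestStandardizeFeatures:
    def test_median_centering_and_clipping(self, rng):
        X = rng.normal(size=(200, 3))
        X[0, 0] = 1e6  # wild outlier
        Z, med, scale = standardize_features(X)
        assert np.allclose(np.median(Z, axis=0), 0.0, atol=0.05)
        assert np.abs(Z).max() <= 20.0

    def test_minority_not_compressed(self, rng):
        """A 2% far-away compartment keeps a large standardized offset
        (a plain z-score would cap it near 1/sqrt(f(1-f)) ~ 7)."""
        x = np.concatenate([rng.normal(0, 1, 490), rng.normal(60, 1, 10)])
        Z, _, _ = standardize_features(x[:, None])
        assert Z[-10:, 0].mean() > 20 * 0.9  # at the winsor cap

    def test_constant_feature_is_safe(self):
        Z, _, _ = standardize_features(np.ones((50, 2)))
        assert np.allclose(Z, 0.0)
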