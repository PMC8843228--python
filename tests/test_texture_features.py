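"""GLCM, Haralick and windowed feature extraction."""

import numpy as np
import pytest

from necromap.texture_features import (FEATURE_NAMES, HARALICK_NAMES,
                                       FeatureSpec, compute_glcm,
                                       extract_feature_stack,
                                       haralick_features,
                                       quantize_gray_levels,
                                       statistical_features)

from oracles import brute_glcm, brute_haralick


class TestQuantization:
    def test_integer_range_maps_to_floor_plus_one(self):
        vals = np.arange(100.0).reshape(10, 10)
        lv = quantize_gray_levels(vals, np.ones((10, 10), bool), 100)
        assert np.array_equal(lv.ravel(), np.arange(100) // 1 + 1)
        assert lv.min() == 1 and lv.max() == 100

    def test_constant_region_collapses_to_level_one(self):
        with pytest.warns(UserWarning):
            lv = quantize_gray_levels(np.full((4, 4), 3.0),
                                      np.ones((4, 4), bool), 50)
        assert (lv == 1).all()

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            quantize_gray_levels(np.zeros((4, 4)), np.ones((4, 4), bool), 1)

    def test_range_comes_from_mask(self):
        vals = np.zeros((4, 4))
        vals[0, 0] = 1000.0  # outside mask: clips to top level
        mask = np.ones((4, 4), bool)
        mask[0, 0] = False
        vals[mask] = np.linspace(0, 10, mask.sum())
        lv = quantize_gray_levels(vals, mask, 10)
        assert lv[0, 0] == 10


class TestGLCM:
    def test_constant_window_single_entry(self):
        P = compute_glcm(np.full((3, 3), 5, dtype=int), 10)
        assert P[4, 4] == 1.0 and P.sum() == 1.0

    def test_symmetric_and_normalized(self, rng):
        for _ in range(20):
            win = rng.integers(1, 9, size=(5, 5))
            P = compute_glcm(win, 8)
            assert abs(P.sum() - 1.0) < 1e-12
            assert np.allclose(P, P.T)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(50):
            win = rng.integers(1, 7, size=(5, 5))
            assert np.allclose(compute_glcm(win, 6), brute_glcm(win, 6),
                               atol=1e-12)

    def test_out_of_range_levels_rejected(self):
        with pytest.raises(ValueError):
            compute_glcm(np.array([[0, 1], [1, 2]]), 4)


class TestHaralick:
    def test_constant_window_degenerate_values(self):
        P = compute_glcm(np.full((3, 3), 2, dtype=int), 5)
        h = dict(zip(HARALICK_NAMES, haralick_features(P)))
        assert h["contrast"] == 0 and h["dissimilarity"] == 0
        assert h["energy"] == 1 and h["entropy"] == 0
        assert h["homogeneity"] == 1 and h["maximum_probability"] == 1
        assert h["correlation"] == 0 and h["imc1"] == 0  # degenerate -> 0

    def test_bounds_on_random_glcms(self, rng):
        for _ in range(50):
            win = rng.integers(1, 11, size=(7, 7))
            h = dict(zip(HARALICK_NAMES,
                         haralick_features(compute_glcm(win, 10))))
            assert 0 < h["energy"] <= 1
            assert h["entropy"] >= 0
            assert 0 < h["homogeneity"] <= 1

    def test_matches_textbook_oracle(self, rng):
        for G in (6, 12):
            for _ in range(30):
                win = rng.integers(1, G + 1, size=(5, 5))
                P = compute_glcm(win, G)
                assert np.allclose(haralick_features(P), brute_haralick(P),
                                   atol=1e-10), (G, win)


class TestStatisticalFeatures:
    def test_hand_computed_moments(self):
        m = statistical_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert m[0] == 2.5 and m[1] == 1.25

    def test_constant_window(self):
        assert np.array_equal(statistical_features(np.full((3, 3), 7.0)),
                              [7.0, 0.0, 0.0, 0.0])

    def test_symmetric_values_have_zero_skewness(self):
        m = statistical_features(np.array([-2.0, -1.0, 1.0, 2.0]))
        assert abs(m[2]) < 1e-12


class TestExtractStack:
    def test_feature_vector_has_24_entries(self, rng):
        img = rng.normal(size=(12, 12))
        mask = np.zeros((12, 12), bool)
        mask[6, 6] = True
        st = extract_feature_stack(img, mask, FeatureSpec(W=3, G=8))
        assert st.X.shape == (1, 24)
        assert len(FEATURE_NAMES) == 24 == 1 + 4 + 19

    def test_translation_invariance(self, rng):
        img = rng.normal(100, 10, size=(20, 20))
        mask = np.zeros((20, 20), bool)
        mask[8:12, 8:12] = True
        a = extract_feature_stack(img, mask, FeatureSpec(W=3, G=16))
        img2 = np.roll(img, (2, 3), axis=(0, 1))
        mask2 = np.roll(mask, (2, 3), axis=(0, 1))
        b = extract_feature_stack(img2, mask2, FeatureSpec(W=3, G=16))
        assert np.allclose(a.X, b.X)

    def test_empty_aoi_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_feature_stack(rng.normal(size=(8, 8)),
                                  np.zeros((8, 8), bool), FeatureSpec())

    def test_stack_matches_per_window_reference(self, rng):
        """The compiled kernel equals the per-window numpy computation."""
        img = rng.normal(50, 12, size=(16, 16))
        mask = np.zeros((16, 16), bool)
        mask[3:13, 3:13] = True
        for W, G in ((3, 8), (9, 30), (15, 64)):
            st = extract_feature_stack(img, mask, FeatureSpec(W=W, G=G))
            levels = quantize_gray_levels(img, mask, G)
            h = W // 2
            for i in rng.choice(st.q, size=10, replace=False):
                x, y = st.positions[i]
                x0, x1 = max(x - h, 0), min(x + h + 1, 16)
                y0, y1 = max(y - h, 0), min(y + h + 1, 16)
                ref = np.concatenate([
                    [img[x, y]],
                    statistical_features(img[x0:x1, y0:y1]),
                    haralick_features(
                        compute_glcm(levels[x0:x1, y0:y1], G))])
                assert np.allclose(st.X[i], ref, atol=1e-9, rtol=1e-9)

    def test_larger_windows_smooth_feature_maps(self, small_case):
        """Bigger W reduces the spatial variance of texture maps."""
        case, _ = small_case
        img = case.poi_image("PC")
        aoi = case.aoi()
        idx_contrast = FEATURE_NAMES.index("contrast")
        idx_entropy = FEATURE_NAMES.index("entropy")
        var = {}
        for W in (3, 9, 15):
            st = extract_feature_stack(img, aoi, FeatureSpec(W=W, G=50))
            var[W] = (np.var(st.X[:, idx_contrast]),
                      np.var(st.X[:, idx_entropy]))
        # normalized spatial variability shrinks as the window grows
        for k in (0, 1):
            cv = {W: var[W][k] for W in (3, 9, 15)}
            assert cv[15] <= cv[3]
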