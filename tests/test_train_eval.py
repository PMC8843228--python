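"""Weight optimization, metrics, responder rule and VOI estimation."""

import numpy as np
import pytest

from necromap.core_io import SUBSETS, SubsetSpec
from necromap.fcm_fusion import WeightVector
from necromap.train_eval import (TrainedModel, classify_responder,
                                 dice_coefficient, enumerate_weight_grid,
                                 estimate_voi_necrosis, objective_value,
                                 optimize_weights, overlap_coefficient,
                                 select_wg)

from oracles import (compositions, exhaustive_weight_search, stars_and_bars)


class TestWeightGrid:
    def test_single_map(self):
        grid = enumerate_weight_grid(1, 0.25)
        assert grid.shape == (1, 1) and grid[0, 0] == 1.0

    def test_two_maps_half_step(self):
        grid = enumerate_weight_grid(2, 0.5)
        assert {tuple(r) for r in grid} == {(0.0, 1.0), (0.5, 0.5),
                                            (1.0, 0.0)}

    @pytest.mark.parametrize("s,t", [(2, 0.5), (3, 0.25), (3, 0.125),
                                     (4, 0.2), (11, 0.5)])
    def test_counts_match_stars_and_bars(self, s, t):
        grid = enumerate_weight_grid(s, t)
        M = round(1 / t)
        assert grid.shape[0] == stars_and_bars(M, s)
        assert np.allclose(grid.sum(axis=1), 1.0)

    def test_lexicographic_order(self):
        grid = enumerate_weight_grid(3, 0.25)
        as_tuples = [tuple(r) for r in np.round(grid / 0.25).astype(int)]
        assert as_tuples == sorted(as_tuples)
        assert as_tuples == list(compositions(4, 3))

    def test_non_dividing_step_rejected(self):
        with pytest.raises(ValueError):
            enumerate_weight_grid(3, 0.3)

    def test_cap_enforced(self):
        with pytest.raises(ValueError, match="coarser"):
            enumerate_weight_grid(11, 0.01)


class TestObjectives:
    def test_hand_values(self):
        est, tru = [12.0, 24.0, 39.0], [10.0, 20.0, 30.0]
        assert objective_value(est, tru, "min_avg") == pytest.approx(5.0)
        assert objective_value(est, tru, "min_max") == pytest.approx(9.0)

    def test_perfect_predictions(self):
        assert objective_value([1.0, 2.0], [1.0, 2.0], "min_avg") == 0.0
        assert objective_value([1.0, 2.0], [1.0, 2.0], "min_max") == 0.0

    def test_single_case_objectives_coincide(self, rng):
        e, t = [float(rng.uniform(0, 100))], [float(rng.uniform(0, 100))]
        assert objective_value(e, t, "min_avg") == \
            objective_value(e, t, "min_max")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            objective_value([], [], "min_avg")


class TestOptimizeWeights:
    @pytest.mark.parametrize("s,invt", [(2, 4), (3, 4), (3, 8)])
    @pytest.mark.parametrize("objective", ["min_avg", "min_max"])
    def test_matches_exhaustive_oracle(self, rng, s, invt, objective):
        t = 1.0 / invt
        U_list = [rng.uniform(size=(25, s)) for _ in range(3)]
        truths = [30.0, 60.0, 85.0]
        wvec, val, _ = optimize_weights(U_list, truths, t=t,
                                        objective=objective)
        _, val_oracle = exhaustive_weight_search(U_list, truths, t,
                                                 objective)
        assert val == pytest.approx(val_oracle, abs=1e-9)

    def test_cross_objective_dominance(self, rng):
        U_list = [rng.uniform(size=(30, 3)) for _ in range(4)]
        truths = [20.0, 45.0, 70.0, 95.0]
        _, avg_at_avg, N_avg = optimize_weights(U_list, truths, t=0.25,
                                                objective="min_avg")
        w_max, _, N_max = optimize_weights(U_list, truths, t=0.25,
                                           objective="min_max")
        f_avg_of_max = np.mean(np.abs(np.asarray(N_max) - truths))
        f_max_of_avg = np.max(np.abs(np.asarray(N_avg) - truths))
        f_max_at_max = np.max(np.abs(np.asarray(N_max) - truths))
        assert avg_at_avg <= f_avg_of_max + 1e-9
        assert f_max_at_max <= f_max_of_avg + 1e-9


class TestSelectWG:
    def test_single_pair(self):
        assert select_wg({(9, 100): 3.0}) == (9, 100)

    def test_all_equal_breaks_to_smallest(self):
        res = {wg: 1.0 for wg in [(3, 50), (3, 100), (9, 50), (15, 200)]}
        assert select_wg(res) == (3, 50)

    def test_argmin(self):
        assert select_wg({(3, 50): 5.0, (9, 100): 2.0,
                          (15, 200): 7.0}) == (9, 100)

    def test_default_grid_has_nine_cells(self):
        from necromap.train_eval import DEFAULT_WG_GRID
        assert len(DEFAULT_WG_GRID) == 9


class TestSetMetrics:
    def test_identical_sets(self, rng):
        a = rng.random(50) < 0.4
        a[0] = True
        assert dice_coefficient(a, a) == 1.0
        assert overlap_coefficient(a, a) == 1.0

    def test_disjoint_sets(self):
        a = np.array([True, False, False])
        b = np.array([False, True, False])
        assert dice_coefficient(a, b) == 0.0
        assert overlap_coefficient(a, b) == 0.0

    def test_hand_values_and_containment(self):
        a = np.zeros(200, bool)
        b = np.zeros(200, bool)
        a[:60] = True
        b[:100] = True
        assert dice_coefficient(a, b) == pytest.approx(2 * 60 / 160)
        assert overlap_coefficient(a, b) == 1.0  # a within b

    def test_dice_bounded_by_overlap(self, rng):
        for _ in range(1000):
            a = rng.random(40) < rng.uniform(0.1, 0.9)
            b = rng.random(40) < rng.uniform(0.1, 0.9)
            if a.sum() and b.sum():
                assert dice_coefficient(a, b) <= \
                    overlap_coefficient(a, b) + 1e-12

    def test_empty_set_conventions(self):
        empty = np.zeros(5, bool)
        some = np.array([True, False, False, False, False])
        assert dice_coefficient(empty, empty) == 1.0
        assert np.isnan(overlap_coefficient(empty, some))


class TestResponder:
    @pytest.mark.parametrize("n,label", [(90.0, "good"), (89.9, "poor"),
                                         (100.0, "good"), (0.0, "poor")])
    def test_threshold(self, n, label):
        assert classify_responder(n) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_responder(101.0)


def _toy_model(anchor_refs):
    """A minimal hand-built fusion model over PC and ADC original values."""
    return TrainedModel(
        subset=SubsetSpec("toy", ("PC", "ADC")), objective="min_avg",
        wg=(3, 50), weights=WeightVector([0.5, 0.5]),
        members=("PC", "ADC"),
        selected={"PC": [0, 1], "ADC": [0, 1]},
        centroids={}, directions={},
        polarity={"PC": ([0, 1], np.array([-1.0, -1.0])),
                  "ADC": ([0, 1], np.array([1.0, 1.0]))},
        anchor_refs=anchor_refs, training_objective=0.0)


class TestVOIEstimation:
    def _refs(self):
        # raw class means of (original, mean) for PC and ADC phantoms
        return {"PC": (np.array([90.0, 90.0]), np.array([180.0, 180.0])),
                "ADC": (np.array([2.0e-3, 2.0e-3]),
                        np.array([1.1e-3, 1.1e-3]))}

    def test_uniform_fraction_voi_close_to_aoi(self, small_case):
        case, truth = small_case
        model = _toy_model(self._refs())
        n_voi, volume = estimate_voi_necrosis(model, case, seed=0)
        assert n_voi == pytest.approx(truth.voi_fraction, abs=4.0)
        # per-construction the slice fractions are uniform, so the POI
        # estimate and the volume estimate agree closely
        assert abs(n_voi - truth.aoi_fraction) <= 4.0
        assert volume.shape == case.voi.shape

    def test_all_viable_phantom_gives_zero(self):
        from conftest import small_config
        from necromap.param_maps import derive_parametric_maps
        from necromap.phantom import generate_phantom
        case, _ = generate_phantom(small_config(necrosis_fraction=0.0,
                                                seed=2))
        derive_parametric_maps(case)
        model = _toy_model(self._refs())
        n_voi, _ = estimate_voi_necrosis(model, case, seed=0)
        assert n_voi == 0.0

    def test_all_necrotic_phantom_gives_hundred(self):
        from conftest import small_config
        from necromap.param_maps import derive_parametric_maps
        from necromap.phantom import generate_phantom
        case, _ = generate_phantom(small_config(necrosis_fraction=100.0,
                                                seed=2))
        derive_parametric_maps(case)
        model = _toy_model(self._refs())
        n_voi, _ = estimate_voi_necrosis(model, case, seed=0)
        assert n_voi == 100.0

    def test_missing_voi_rejected(self, small_case):
        case, _ = small_case
        model = _toy_model(self._refs())
        import copy
        bare = copy.copy(case)
        bare.voi = None
        with pytest.raises(ValueError):
            estimate_voi_necrosis(model, bare)
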