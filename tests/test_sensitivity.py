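import numpy as np
import pytest

import striatum_mvpa as sm
from striatum_mvpa.decoder import PairwiseClassifierSet
from striatum_mvpa.sensitivity import RFEConfig

from conftest import make_roi_dataset, roi_samples


def _models(weights):
    weights = np.asarray(weights, dtype=float)
    n_pairs = weights.shape[0]
    classes = np.array([1, 2, 3, 4])[: {1: 2, 3: 3, 6: 4}[n_pairs]]
    from itertools import combinations
    pairs = list(combinations(classes.tolist(), 2))
    return PairwiseClassifierSet(classes, pairs, weights,
                                 np.zeros(n_pairs))


class TestSensitivity:
    def test_hand_computed_mean_square(self):
        # one voxel, weights (1, -1, 2, 0, 0, 0) across the six pairs
        w = np.array([[1.0], [-1.0], [2.0], [0.0], [0.0], [0.0]])
        assert sm.compute_sensitivity(_models(w))[0] == pytest.approx(1.0)

    def test_zero_weights_and_single_pair(self):
        assert sm.compute_sensitivity(_models(np.zeros((6, 3)))).max() == 0
        w = np.array([[0.5, -2.0]])
        assert sm.compute_sensitivity(_models(w)) == pytest.approx(
            [0.25, 4.0])

    def test_invariant_to_weight_sign_flips(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal((6, 7))
        flipped = w * np.where(rng.random((6, 1)) < 0.5, -1, 1)
        assert np.allclose(sm.compute_sensitivity(_models(w)),
                           sm.compute_sensitivity(_models(flipped)))


class TestWeightMaps:
    def test_six_volumes_zero_outside_roi(self, signal_samples):
        maps = sm.full_data_weight_maps(signal_samples)
        pair_maps = {k: v for k, v in maps.items() if k != "sensitivity"}
        assert len(pair_maps) == 6
        outside = np.ones(signal_samples.grid_shape, dtype=bool)
        outside[tuple(signal_samples.voxel_coords.T)] = False
        for vol in maps.values():
            assert vol.shape == signal_samples.grid_shape
            assert np.abs(vol[outside]).max() == 0.0

    def test_sensitivity_volume_is_mean_of_squared_pair_maps(self,
                                                             signal_samples):
        maps = sm.full_data_weight_maps(signal_samples)
        stack = np.stack([v for k, v in maps.items() if k != "sensitivity"])
        assert np.allclose(maps["sensitivity"], (stack ** 2).mean(axis=0))


class TestBackwardElimination:
    def test_three_voxel_toy_has_full_trace(self, noise_samples):
        small = noise_samples.select_voxels([0, 1, 2])
        trace = sm.backward_elimination(small, rfe=RFEConfig())
        assert trace.n_voxels == 3
        assert len(trace.accuracies) == 3
        for row in trace.elimination_order:
            assert sorted(row) == [0, 1, 2]   # a permutation per fold

    def test_accuracy_at_full_roi_equals_whole_roi_loso(self, signal_samples):
        trace = sm.backward_elimination(signal_samples,
                                        rfe=RFEConfig(significance="none"))
        loso = sm.loso_cross_validate(signal_samples)
        assert trace.accuracy_at(signal_samples.n_voxels) == loso.accuracy

    def test_pure_noise_voxel_eliminated_first(self):
        # two clean signal voxels + one pure-noise voxel
        rng = np.random.default_rng(5)
        n_per = 12
        centers = {1: (3, 0), 2: (-3, 0), 3: (0, 3), 4: (0, -3)}
        X = np.vstack([
            np.column_stack([
                rng.normal(centers[c][0], 0.5, n_per),
                rng.normal(centers[c][1], 0.5, n_per),
                rng.standard_normal(n_per),           # the noise voxel
            ]) for c in (1, 2, 3, 4)])
        y = np.repeat([1, 2, 3, 4], n_per)
        trace = sm.backward_elimination((X, y), rfe=RFEConfig(
            significance="none"))
        first_out = trace.elimination_order[:, 0]
        assert (first_out == 2).mean() >= 0.95

    def test_deterministic(self, signal_samples):
        a = sm.backward_elimination(signal_samples,
                                    rfe=RFEConfig(significance="none"))
        b = sm.backward_elimination(signal_samples,
                                    rfe=RFEConfig(significance="none"))
        assert np.array_equal(a.elimination_order, b.elimination_order)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_permutation_significance_on_tiny_problem(self):
        _, mask, ds = make_roi_dataset(n_voxels=5, n_subjects=2,
                                       pattern_sd=2.0, seed=3,
                                       n_informative_voxels=3)
        smat = roi_samples(ds, mask)
        trace = sm.backward_elimination(
            smat, rfe=RFEConfig(significance="permutation",
                                n_permutations=25, seed=1))
        assert trace.p_values.shape == (5,)
        assert ((trace.p_values > 0) & (trace.p_values <= 1)).all()
        assert trace.fdr_significant.dtype == bool

    def test_binomial_p_small_when_accuracy_high(self, signal_samples):
        trace = sm.backward_elimination(signal_samples, rfe=RFEConfig())
        m_best = int(np.argmax(trace.accuracies)) + 1
        if trace.accuracy_at(m_best) > 0.5:
            assert trace.p_values[m_best - 1] < 1e-6


class TestTopSelected:
    def test_always_surviving_voxel_has_maximal_score(self, signal_samples):
        trace = sm.backward_elimination(signal_samples,
                                        rfe=RFEConfig(significance="none"))
        scores = trace.selection_scores(survival_depth=10)
        last = trace.elimination_order[:, -1]
        if len(np.unique(last)) == 1:
            assert scores[last[0]] == trace.n_folds
        assert scores.max() <= trace.n_folds

    def test_exactly_k_entries_and_truncation_warning(self, signal_samples):
        trace = sm.backward_elimination(signal_samples,
                                        rfe=RFEConfig(significance="none"))
        top = sm.top_selected_voxels(trace, k=10)
        assert len(top) == 10
        with pytest.warns(UserWarning, match="truncating"):
            top_all = sm.top_selected_voxels(trace, k=10_000)
        assert len(top_all) == trace.n_voxels
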