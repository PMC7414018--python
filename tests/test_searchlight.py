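import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import striatum_mvpa as sm
from striatum_mvpa.assembly import MaskVolume, default_affine
from striatum_mvpa.searchlight import SearchlightConfig, sphere_offsets

from conftest import make_roi_dataset, roi_samples


def _brute_force_sphere(center, maskb, radius_mm, vs):
    out = []
    for p in np.argwhere(maskb):
        if ((p - center) ** 2).sum() * vs ** 2 <= radius_mm ** 2:
            out.append(p)
    return np.array(sorted(map(tuple, out)))


def _full_mask(shape, vs=2.0):
    return MaskVolume(np.ones(shape, dtype=np.int16), default_affine(vs), vs)


class TestSphereGeometry:
    def test_deep_interior_5mm_sphere_has_81_voxels(self):
        mask = _full_mask((11, 11, 11))
        got = sm.sphere_indices((5, 5, 5), mask, 5.0)
        assert len(got) == 81
        expected = _brute_force_sphere(np.array([5, 5, 5]), mask.binary(),
                                       5.0, 2.0)
        assert np.array_equal(np.array(sorted(map(tuple, got))), expected)

    def test_radius_below_voxel_size_keeps_only_center(self):
        mask = _full_mask((5, 5, 5))
        got = sm.sphere_indices((2, 2, 2), mask, 1.5)
        assert len(got) == 1 and tuple(got[0]) == (2, 2, 2)

    def test_boundary_sphere_is_strict_subset_of_interior(self):
        mask = _full_mask((11, 11, 11))
        interior = sm.sphere_indices((5, 5, 5), mask, 5.0)
        corner = sm.sphere_indices((0, 0, 0), mask, 5.0)
        assert 0 < len(corner) < len(interior)

    def test_center_outside_mask_raises(self):
        data = np.zeros((5, 5, 5), dtype=np.int16)
        data[2, 2, 2] = 1
        mask = MaskVolume(data, default_affine(2.0), 2.0)
        with pytest.raises(ValueError, match="outside"):
            sm.sphere_indices((0, 0, 0), mask, 5.0)

    @given(radius=st.floats(1.0, 8.0))
    @settings(max_examples=25, deadline=None)
    def test_sphere_size_monotone_in_radius(self, radius):
        a = len(sphere_offsets(radius, 2.0))
        b = len(sphere_offsets(radius + 1.0, 2.0))
        assert b >= a

    def test_offsets_symmetric_under_axis_permutation(self):
        offs = {tuple(o) for o in sphere_offsets(5.0, 2.0)}
        for o in list(offs):
            assert (o[1], o[2], o[0]) in offs and (o[0], -o[1], o[2]) in offs

    def test_brute_force_oracle_on_random_mask(self):
        rng = np.random.default_rng(4)
        data = (rng.random((9, 9, 9)) < 0.5).astype(np.int16)
        data[4, 4, 4] = 1
        mask = MaskVolume(data, default_affine(2.0), 2.0)
        got = sm.sphere_indices((4, 4, 4), mask, 5.0)
        expected = _brute_force_sphere(np.array([4, 4, 4]), mask.binary(),
                                       5.0, 2.0)
        assert np.array_equal(np.array(sorted(map(tuple, got))), expected)


class TestSearchlightMap:
    def test_map_support_is_exactly_the_roi(self, signal_samples):
        slm = sm.searchlight_map(signal_samples, SearchlightConfig())
        vol = slm.to_volume()
        defined = ~np.isnan(vol)
        roi = np.zeros(signal_samples.grid_shape, dtype=bool)
        roi[tuple(signal_samples.voxel_coords.T)] = True
        assert np.array_equal(defined, roi)
        assert ((slm.accuracies >= 0) & (slm.accuracies <= 1)).all()

    def test_tiny_radius_reduces_to_single_voxel_decoding(self, signal_samples):
        slm = sm.searchlight_map(signal_samples,
                                 SearchlightConfig(radius_mm=0.5))
        assert (slm.sphere_sizes == 1).all()
        v = 7
        solo = sm.loso_cross_validate(
            (signal_samples.values[:, [v]], signal_samples.labels))
        assert slm.accuracies[v] == solo.accuracy

    def test_whole_roi_demeaning_equals_per_sphere_demeaning(self):
        # demeaning is voxelwise, so demean-then-subset == subset-then-demean
        _, mask, ds = make_roi_dataset(n_voxels=30, pattern_sd=1.0, seed=6)
        raw = sm.extract_roi_samples(ds, mask, [1])
        whole = sm.demean_within_block(raw)
        cols = np.arange(5, 15)
        a = whole.select_voxels(cols)
        b = sm.demean_within_block(raw.select_voxels(cols))
        assert np.allclose(a.values, b.values, atol=1e-12)


class TestPooledNull:
    def test_pool_size_and_pvalue_range(self, noise_samples):
        small = noise_samples.select_voxels(np.arange(12))
        cfg = SearchlightConfig(n_perm_per_voxel=4, seed=2)
        pooled = sm.pooled_permutation_threshold(small, cfg)
        assert pooled.null_accuracies.size == 12 * 4
        assert ((pooled.p_values > 0) & (pooled.p_values <= 1)).all()

    def test_no_rejection_when_all_accuracies_at_null_level(self,
                                                            noise_samples):
        small = noise_samples.select_voxels(np.arange(10))
        pooled = sm.pooled_permutation_threshold(
            small, SearchlightConfig(n_perm_per_voxel=5, seed=3))
        if not pooled.significant.any():
            assert np.isnan(pooled.accuracy_threshold)
        else:  # any rejection must sit above the pool's bulk
            assert pooled.accuracy_threshold >= np.quantile(
                pooled.null_accuracies, 0.9)


class TestTerritoryTable:
    def _setup(self):
        nuclei = np.zeros((6, 6, 6), dtype=np.int16)
        nuclei[1:4, 1:4, 1:4] = 1
        territories = np.zeros_like(nuclei)
        territories[1:4, 1:4, 1:4] = 1
        territories[2, :, :] *= 0
        territories[2, 1:4, 1:4] = 3
        territories[3, 1:4, 1:4] = 5
        vs = 2.0
        return (MaskVolume(nuclei, default_affine(vs), vs, {1: "left_putamen"}),
                MaskVolume(territories, default_affine(vs), vs,
                           {1: "limbic", 3: "rostral_motor", 5: "parietal"}))

    def test_counts_and_percentages(self):
        nuclei, territories = self._setup()
        sig = np.zeros((6, 6, 6), dtype=bool)
        sig[1, 1, 1] = sig[1, 2, 1] = True      # territory 1 (x == 1)
        sig[2, 1, 1] = True                      # territory 3
        sig[3, 1, 1] = True                      # territory 5
        table = sm.quantify_by_atlas(sig, nuclei, territories)
        by = table.set_index("territory")
        assert by.loc["limbic", "n_significant"] == 2
        assert by.loc["limbic", "percent"] == pytest.approx(50.0)
        assert by.loc["rostral_motor", "percent"] == pytest.approx(25.0)
        assert by.loc["parietal", "percent"] == pytest.approx(25.0)
        assert table["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_empty_mask_gives_zero_table(self):
        nuclei, territories = self._setup()
        table = sm.quantify_by_atlas(np.zeros((6, 6, 6), dtype=bool),
                                     nuclei, territories)
        assert (table["n_significant"] == 0).all()
        assert (table["percent"] == 0).all()

    def test_unlabeled_significant_voxels_warned_and_counted(self):
        nuclei, territories = self._setup()
        territories.data[1, 1, 1] = 0            # strip one label
        sig = np.zeros((6, 6, 6), dtype=bool)
        sig[1, 1, 1] = True
        with pytest.warns(UserWarning, match="no territory label"):
            table = sm.quantify_by_atlas(sig, nuclei, territories)
        assert table.set_index("territory").loc["unlabeled",
                                                "n_significant"] == 1
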