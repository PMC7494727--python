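"""Segmentation operations against brute-force oracles and phantom truth."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chalkct as ck
from chalkct.segmentation import fill_holes_3d

from conftest import (
    bfs_flood_fill,
    match_labels_to_truth,
    random_blob_mask,
    union_find_components,
)

SPACING = (0.01, 0.01, 0.01)


def as_mask(data):
    return ck.BinaryMask(data, SPACING)


class TestThresholdBand:
    def test_uniform_volume_inside_band_is_all_true(self):
        vol = ck.VoxelVolume(np.full((3, 3, 3), 200.0), SPACING)
        assert ck.threshold_band(vol, 150, 255).data.all()

    def test_band_is_closed_at_both_ends(self):
        vol = ck.VoxelVolume(np.array([[[99, 100, 150, 151]]], float), SPACING)
        got = ck.threshold_band(vol, 100, 150).data[0, 0]
        np.testing.assert_array_equal(got, [False, True, True, False])

    def test_inverted_band_raises(self):
        vol = ck.VoxelVolume(np.zeros((2, 2, 2)), SPACING)
        with pytest.raises(ValueError):
            ck.threshold_band(vol, 255, 0)

    def test_midpoint_band_recovers_grain_truth(self, small_phantom):
        spec, vol, truth = small_phantom
        lo = (spec.mu_clay + spec.mu_chalk) / 2
        mask = ck.threshold_band(vol, lo, float(vol.data.max()))
        np.testing.assert_array_equal(mask.data, truth.grain_labels.data > 0)


class TestAutoThreshold:
    def test_two_value_mixture_cut_between(self):
        data = np.concatenate([np.zeros(500), np.full(500, 200.0)])
        vol = ck.VoxelVolume(data.reshape(10, 10, 10), SPACING)
        (cut,) = ck.auto_threshold(vol, 2)
        assert 0 < cut < 200

    def test_noiseless_four_class_cuts_between_class_means(self, small_phantom):
        spec, vol, _ = small_phantom
        cuts = ck.auto_threshold(vol, 4)
        means = [spec.mu_air, spec.mu_clay, spec.mu_chalk, spec.mu_endosperm]
        assert len(cuts) == 3
        for cut, lo, hi in zip(cuts, means[:-1], means[1:]):
            assert lo < cut < hi

    def test_constant_volume_raises(self):
        vol = ck.VoxelVolume(np.full((4, 4, 4), 7.0), SPACING)
        with pytest.raises(ValueError, match="degenerate"):
            ck.auto_threshold(vol, 2)


class TestContrastWindow:
    def test_full_window_is_identity_up_to_rounding(self):
        data = np.arange(256, dtype=float).reshape(1, 16, 16)
        out = ck.apply_contrast_window(ck.VoxelVolume(data, SPACING), 128, 256)
        assert np.all(np.abs(out.data - data) <= 1.0)

    def test_center_maps_to_midpoint(self):
        vol = ck.VoxelVolume(np.full((1, 1, 1), 70.0), SPACING)
        out = ck.apply_contrast_window(vol, 70, 100)
        assert out.data[0, 0, 0] == pytest.approx(127.5)

    def test_saturates_outside_window(self):
        vol = ck.VoxelVolume(np.array([[[0.0, 200.0]]]), SPACING)
        out = ck.apply_contrast_window(vol, 100, 50)
        np.testing.assert_allclose(out.data[0, 0], [0.0, 255.0])

    @settings(derandomize=True, max_examples=25)
    @given(
        center=st.floats(-50, 300),
        width=st.floats(1e-3, 500),
        seed=st.integers(0, 1000),
    )
    def test_monotone_in_intensity(self, center, width, seed):
        rng = np.random.default_rng(seed)
        data = rng.uniform(-10, 260, (4, 4, 4))
        out = ck.apply_contrast_window(
            ck.VoxelVolume(data, SPACING), center, width
        ).data
        order = np.argsort(data.ravel())
        assert np.all(np.diff(out.ravel()[order]) >= 0)

    def test_nonpositive_width_raises(self):
        vol = ck.VoxelVolume(np.zeros((2, 2, 2)), SPACING)
        with pytest.raises(ValueError, match="width"):
            ck.apply_contrast_window(vol, 100, 0)


class TestRegionGrow:
    @staticmethod
    def _two_blobs():
        data = np.zeros((10, 10, 10), dtype=bool)
        data[1:4, 1:4, 1:4] = True
        data[6:9, 6:9, 6:9] = True
        return data

    def test_seed_selects_only_its_blob(self):
        data = self._two_blobs()
        got = ck.region_grow(as_mask(data), [(2, 2, 2)], 26)
        expected = np.zeros_like(data)
        expected[1:4, 1:4, 1:4] = True
        np.testing.assert_array_equal(got.data, expected)

    def test_seeds_in_both_blobs_select_both(self):
        data = self._two_blobs()
        got = ck.region_grow(as_mask(data), [(2, 2, 2), (7, 7, 7)], 26)
        np.testing.assert_array_equal(got.data, data)

    def test_seed_outside_mask_raises(self):
        data = self._two_blobs()
        with pytest.raises(ValueError, match=r"seed not in mask.*5, 5, 5"):
            ck.region_grow(as_mask(data), [(5, 5, 5)], 26)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_bfs_oracle_on_random_masks(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(30):
            mask = random_blob_mask(rng, (12, 12, 12))
            true_idx = np.argwhere(mask)
            if len(true_idx) == 0:
                continue
            seeds = [tuple(true_idx[i]) for i in
                     rng.choice(len(true_idx), size=min(3, len(true_idx)),
                                replace=False)]
            got = ck.region_grow(as_mask(mask), seeds, connectivity)
            oracle = bfs_flood_fill(mask, seeds, connectivity)
            np.testing.assert_array_equal(got.data, oracle)


class TestLabelGrains:
    def test_phantom_grains_match_truth_counts(self, small_phantom):
        spec, vol, truth = small_phantom
        lo = (spec.mu_clay + spec.mu_chalk) / 2
        mask = ck.threshold_band(vol, lo, float(vol.data.max()))
        labels = ck.label_grains(mask, 26)
        assert labels.n_labels == 3
        mapping = match_labels_to_truth(labels, truth.grain_labels)
        for tid, lid in mapping.items():
            assert np.sum(labels.data == lid) == np.sum(
                truth.grain_labels.data == tid
            )

    def test_empty_mask_gives_zero_labels(self):
        labels = ck.label_grains(as_mask(np.zeros((5, 5, 5), bool)))
        assert labels.n_labels == 0

    def test_labels_ordered_by_descending_size(self):
        data = np.zeros((12, 12, 12), dtype=bool)
        data[8:11, 8:11, 8:11] = True  # 27 voxels, later in scan order
        data[0:2, 0:2, 0:2] = True  # 8 voxels, earlier
        labels = ck.label_grains(as_mask(data), 26)
        assert labels.data[9, 9, 9] == 1
        assert labels.data[1, 1, 1] == 2

    def test_min_size_filter_discards_small_components(self):
        data = np.zeros((12, 12, 12), dtype=bool)
        data[0:3, 0:3, 0:3] = True
        data[10, 10, 10] = True
        labels = ck.label_grains(as_mask(data), 26, min_grain_voxels=5)
        assert labels.n_labels == 1
        assert labels.data[10, 10, 10] == 0

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_union_find_oracle(self, connectivity):
        rng = np.random.default_rng(7)
        for _ in range(30):
            mask = random_blob_mask(rng, (12, 12, 12), p=0.35)
            got = ck.label_grains(as_mask(mask), connectivity).data
            oracle = union_find_components(mask, connectivity)
            # same partition up to renumbering
            assert (got > 0).sum() == (oracle > 0).sum()
            pairs = set(zip(got[mask], oracle[mask]))
            assert len(pairs) == len({a for a, _ in pairs})
            assert len(pairs) == len({b for _, b in pairs})


class TestMorphClean:
    def test_solid_ball_unchanged(self):
        ball = ck.rasterize_ellipsoid(
            (0.1, 0.1, 0.1), (0.06,) * 3, (0, 0, 0), (20, 20, 20), SPACING
        )
        out = ck.morph_clean(ball, radius=2, fill_holes_flag=True)
        np.testing.assert_array_equal(out.data, ball.data)

    def test_hollow_shell_fills_to_solid_ball(self):
        outer = ck.rasterize_ellipsoid(
            (0.1, 0.1, 0.1), (0.06,) * 3, (0, 0, 0), (20, 20, 20), SPACING
        )
        inner = ck.rasterize_ellipsoid(
            (0.1, 0.1, 0.1), (0.04,) * 3, (0, 0, 0), (20, 20, 20), SPACING
        )
        shell = as_mask(outer.data & ~inner.data)
        filled = ck.morph_clean(shell, radius=0, fill_holes_flag=True)
        np.testing.assert_array_equal(filled.data, outer.data)

    def test_radius_zero_fill_off_is_identity(self):
        rng = np.random.default_rng(3)
        data = rng.random((8, 8, 8)) < 0.4
        out = ck.morph_clean(as_mask(data), radius=0, fill_holes_flag=False)
        np.testing.assert_array_equal(out.data, data)

    def test_hole_filling_matches_border_flood_fill_complement(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            mask = random_blob_mask(rng, (14, 14, 14), p=0.45)
            got = fill_holes_3d(as_mask(mask)).data
            # oracle: 6-connected BFS over background from all border voxels
            bg = ~mask
            border_seeds = [
                tuple(v) for v in np.argwhere(bg)
                if 0 in v or v[0] == 13 or v[1] == 13 or v[2] == 13
            ]
            reachable = bfs_flood_fill(bg, border_seeds, 6)
            oracle = mask | (bg & ~reachable)
            np.testing.assert_array_equal(got, oracle)


class TestSegmentChalk:
    @staticmethod
    def _params():
        return ck.SegmentationParams(min_chalk_component_voxels=0)

    def test_centered_ball_recovered_exactly_noiseless(self, small_phantom):
        spec, vol, truth = small_phantom
        grain = ck.BinaryMask(truth.grain_labels.data > 0, vol.spacing)
        chalk = ck.segment_chalk(vol, grain, self._params())
        np.testing.assert_array_equal(chalk.data, truth.chalk_mask.data)

    def test_grain_without_chalk_gives_empty_mask(self, small_phantom):
        spec, vol, truth = small_phantom
        # isolate a chalk-free grain
        for tid in range(1, 4):
            region = truth.grain_labels.data == tid
            if not np.any(truth.chalk_mask.data & region):
                break
        grain = ck.BinaryMask(region, vol.spacing)
        chalk = ck.segment_chalk(vol, grain, self._params())
        assert chalk.count() == 0

    def test_output_is_subset_of_grain_mask(self, small_phantom):
        _, vol, truth = small_phantom
        grain = ck.BinaryMask(truth.grain_labels.data > 0, vol.spacing)
        chalk = ck.segment_chalk(vol, grain, ck.SegmentationParams())
        assert not np.any(chalk.data & ~grain.data)

    def test_empty_grain_mask_raises(self, small_phantom):
        _, vol, _ = small_phantom
        empty = ck.BinaryMask(np.zeros(vol.shape, bool), vol.spacing)
        with pytest.raises(ValueError, match="no grain region"):
            ck.segment_chalk(vol, empty, self._params())


class TestSegmentSample:
    def test_three_grain_phantom_one_chalky(self, small_phantom):
        _, vol, truth = small_phantom
        labels, chalk = ck.segment_sample(vol)
        assert labels.n_labels == 3
        touched = set(np.unique(labels.data[chalk.data])) - {0}
        assert len(touched) == 1
        assert not np.any(chalk.data & (labels.data == 0))

    def test_all_air_volume_raises_no_grains(self):
        vol = ck.VoxelVolume(np.zeros((20, 20, 20)), SPACING)
        with pytest.raises(ValueError, match="no grains detected"):
            ck.segment_sample(vol)

    def test_air_and_clay_only_raises_no_grains(self):
        # two background classes but nothing grain-sized above the cut
        data = np.zeros((20, 20, 20))
        data[5:15] = 40.0
        with pytest.raises(ValueError, match="no grains detected"):
            ck.segment_sample(ck.VoxelVolume(data, SPACING),
                              ck.SegmentationParams(min_grain_voxels=5000))

    def test_clay_block_does_not_change_grain_labels_or_chalk(self):
        kw = dict(spacing_mm=0.02, semi_axes_mm=(0.4, 0.2, 0.18), rng_seed=5)
        with_clay = ck.multigrain_spec(3, 1, clay=True, **kw)
        without = ck.multigrain_spec(3, 1, clay=False, **kw)
        vol_a, _ = ck.generate_phantom(with_clay)
        vol_b, _ = ck.generate_phantom(without)
        lab_a, chalk_a = ck.segment_sample(vol_a)
        lab_b, chalk_b = ck.segment_sample(vol_b)
        np.testing.assert_array_equal(lab_a.data, lab_b.data)
        np.testing.assert_array_equal(chalk_a.data, chalk_b.data)

    def test_label_count_invariant_to_intensity_rescaling(self, small_phantom):
        _, vol, _ = small_phantom
        scaled = ck.VoxelVolume(vol.data * 3.0 + 17.0, vol.spacing)
        labels, _ = ck.segment_sample(vol)
        labels_scaled, _ = ck.segment_sample(scaled)
        assert labels.n_labels == labels_scaled.n_labels
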