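"""Linewidth model and MRSI brain-coverage metric."""

import numpy as np
import pytest

from b0shim import (
    BrainMask,
    FieldMap,
    LinewidthModel,
    block_partition,
    compute_coverage,
    region_coverage,
    voxel_linewidth,
)

MODEL = LinewidthModel()  # 9 Hz baseline, 18 Hz threshold


class TestBlockPartition:
    def test_study_voxel_is_125_pixels(self):
        grid = block_partition((2.4, 2.4, 2.0), (12.0, 12.0, 10.0))
        assert grid.block_dims == (5, 5, 5)
        assert grid.pixels_per_voxel == 125
        assert grid.voxel_volume_cc == pytest.approx(1.44)

    def test_high_resolution_voxel_rounds_to_eight_pixels(self):
        grid = block_partition((2.4, 2.4, 2.0), (4.5, 4.5, 4.5))
        assert grid.block_dims == (2, 2, 2)
        assert grid.voxel_volume_cc == pytest.approx(0.092, abs=0.001)

    def test_subpixel_voxel_floors_at_one(self):
        grid = block_partition((2.4, 2.4, 2.0), (1.0, 1.0, 1.0))
        assert grid.block_dims == (1, 1, 1)

    def test_large_volume_mismatch_warns(self):
        with pytest.warns(UserWarning):
            block_partition((2.4, 2.4, 2.0), (3.5, 3.5, 3.5))

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            block_partition((2.4, 2.4, 2.0), (0.0, 12.0, 10.0))


class TestVoxelLinewidth:
    def test_uniform_block_gives_baseline(self):
        assert voxel_linewidth(np.full(125, 3.7), MODEL) == pytest.approx(9.0)

    def test_two_point_block(self):
        vals = np.array([6.0] * 10 + [-6.0] * 10)
        assert voxel_linewidth(vals, MODEL) == pytest.approx(15.0)

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            voxel_linewidth(np.array([]), MODEL)

    def test_baseline_must_be_below_threshold(self):
        with pytest.raises(ValueError):
            LinewidthModel(baseline_hz=20.0, threshold_hz=18.0)


def _volume(data, spacing=(2.4, 2.4, 2.0)):
    fm = FieldMap(np.asarray(data, dtype=float), spacing=spacing)
    mask = BrainMask(np.ones(fm.shape, bool), spacing=spacing)
    return fm, mask


class TestComputeCoverage:
    def test_constant_field_full_coverage(self):
        fm, mask = _volume(np.full((10, 10, 10), 42.0))
        grid = block_partition(fm.spacing, (12.0, 12.0, 10.0))
        cov = compute_coverage(fm, mask, grid, MODEL)
        assert cov.coverage_pct == 100.0
        assert cov.n_usable == cov.n_brain_voxels

    def test_everywhere_noisy_field_zero_coverage(self):
        rng = np.random.default_rng(0)
        # SD far above the 9 Hz headroom in every block
        fm, mask = _volume(rng.normal(0, 60, (10, 10, 10)))
        grid = block_partition(fm.spacing, (12.0, 12.0, 10.0))
        cov = compute_coverage(fm, mask, grid, MODEL)
        assert cov.coverage_pct == 0.0

    def test_block_sd_of_exactly_nine_hz_is_unusable(self):
        # strict < 18 Hz: baseline 9 + SD 9 = 18 is excluded;
        # equal counts of +-9 make the block SD exactly 9
        data = np.zeros((5, 5, 10))
        data[..., :5] = 9.0
        data[..., 5:] = -9.0
        fm, mask = _volume(data)
        grid = block_partition(fm.spacing, (12.0, 12.0, 20.0))
        cov = compute_coverage(fm, mask, grid, MODEL)
        assert np.allclose(cov.linewidth[np.isfinite(cov.linewidth)], 18.0)
        assert cov.coverage_pct == 0.0

    def test_half_usable_counts_as_fifty_percent(self):
        data = np.zeros((5, 5, 10))
        data[:, :, 5::2] = 12.0  # second block: SD 6 -> usable
        data[:, :, 0] = 50.0     # first block: SD >> 9 -> unusable
        fm, mask = _volume(data)
        grid = block_partition(fm.spacing, (12.0, 12.0, 10.0))
        cov = compute_coverage(fm, mask, grid, MODEL)
        assert cov.n_brain_voxels == 2
        assert cov.coverage_pct == pytest.approx(50.0)

    def test_coverage_invariant_to_global_offset(self, default_subject):
        sub = default_subject
        grid = block_partition(sub.fieldmap.spacing, (12.0, 12.0, 10.0))
        c0 = compute_coverage(sub.fieldmap, sub.mask, grid, MODEL)
        shifted = sub.fieldmap.with_data(sub.fieldmap.data + 137.0)
        c1 = compute_coverage(shifted, sub.mask, grid, MODEL)
        assert c1.coverage_pct == c0.coverage_pct
        assert np.array_equal(c0.usable, c1.usable)

    def test_usable_plus_unusable_equals_brain_voxels(self, default_subject):
        sub = default_subject
        grid = block_partition(sub.fieldmap.spacing, (12.0, 12.0, 10.0))
        cov = compute_coverage(sub.fieldmap, sub.mask, grid, MODEL)
        n_unusable = int((cov.brain_voxel & ~cov.usable).sum())
        assert cov.n_usable + n_unusable == cov.n_brain_voxels

    def test_tighter_threshold_never_increases_coverage(self, default_subject):
        sub = default_subject
        grid = block_partition(sub.fieldmap.spacing, (12.0, 12.0, 10.0))
        loose = compute_coverage(sub.fieldmap, sub.mask, grid,
                                 LinewidthModel(9.0, 18.0))
        tight = compute_coverage(sub.fieldmap, sub.mask, grid,
                                 LinewidthModel(9.0, 14.0))
        assert tight.coverage_pct <= loose.coverage_pct

    def test_majority_rule_for_brain_voxels(self):
        data = np.zeros((5, 5, 5))
        fm = FieldMap(data, spacing=(2.4, 2.4, 2.0))
        mask_data = np.zeros((5, 5, 5), bool)
        mask_data[:3] = True  # 75 of 125 pixels: majority -> brain voxel
        cov = compute_coverage(fm, BrainMask(mask_data, spacing=fm.spacing),
                               block_partition(fm.spacing, (12, 12, 10)), MODEL)
        assert cov.n_brain_voxels == 1
        mask_data[:] = False
        mask_data[:2] = True  # 50 of 125: not a majority
        with pytest.raises(ValueError):
            compute_coverage(fm, BrainMask(mask_data, spacing=fm.spacing),
                             block_partition(fm.spacing, (12, 12, 10)), MODEL)

    def test_empty_mask_rejected(self):
        fm, _ = _volume(np.zeros((5, 5, 5)))
        mask = BrainMask(np.zeros((5, 5, 5), bool), spacing=fm.spacing)
        grid = block_partition(fm.spacing, (12.0, 12.0, 10.0))
        with pytest.raises(ValueError):
            compute_coverage(fm, mask, grid, MODEL)


class TestRegionCoverage:
    def test_whole_mask_roi_equals_whole_brain_coverage(self, default_subject):
        sub = default_subject
        grid = block_partition(sub.fieldmap.spacing, (12.0, 12.0, 10.0))
        cov = compute_coverage(sub.fieldmap, sub.mask, grid, MODEL)
        roi = BrainMask(sub.mask.data.copy(), spacing=sub.mask.spacing,
                        origin=sub.mask.origin)
        assert region_coverage(cov, sub.mask, roi) == pytest.approx(
            cov.coverage_pct
        )

    def test_roi_of_usable_voxels_is_fully_covered(self):
        data = np.zeros((5, 5, 10))
        data[:, :, 0] = 50.0  # first block unusable
        fm, mask = _volume(data)
        grid = block_partition(fm.spacing, (12.0, 12.0, 10.0))
        cov = compute_coverage(fm, mask, grid, MODEL)
        roi_data = np.zeros((5, 5, 10), bool)
        roi_data[:, :, 5:] = True  # second (clean) block only
        roi = BrainMask(roi_data, spacing=fm.spacing)
        assert region_coverage(cov, mask, roi) == 100.0

    def test_prefrontal_coverage_worse_than_whole_brain_before_shim(
        self, default_subject
    ):
        # the frontal-sinus dipole sits next to the PFC box
        sub = default_subject
        grid = block_partition(sub.fieldmap.spacing, (12.0, 12.0, 10.0))
        cov = compute_coverage(sub.fieldmap, sub.mask, grid, MODEL)
        pfc = region_coverage(cov, sub.mask, sub.roi_pfc)
        assert pfc < cov.coverage_pct

    def test_disjoint_roi_rejected(self):
        fm, mask = _volume(np.zeros((5, 5, 5)))
        roi = BrainMask(np.zeros((5, 5, 5), bool), spacing=fm.spacing)
        grid = block_partition(fm.spacing, (12.0, 12.0, 10.0))
        cov = compute_coverage(fm, mask, grid, MODEL)
        with pytest.raises(ValueError):
            region_coverage(cov, mask, roi)
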