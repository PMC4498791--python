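"""Segmentation operators: thresholding and region growing on SUV volumes."""

import numpy as np
import pytest

from petgtv import (
    RGParams,
    ROI,
    dsc_between,
    region_grow,
    threshold_fixed,
    threshold_percent_max,
)
from petgtv.phantom import _rasterize_sphere

from conftest import make_volume


@pytest.fixture
def sphere_suv(sphere_phantom):
    """Noiseless 4:1 sphere as an SUV-like volume plus its exact voxel set."""
    pet = sphere_phantom.pet
    inside = _rasterize_sphere(pet.shape, pet.spacing_mm, pet.origin_mm,
                               sphere_phantom.spec.lesions[0])
    return pet, inside, sphere_phantom.truth_masks[0]


def full_roi(vol):
    return ROI((0, 0, 0), vol.shape)


class TestThresholdPercentMax:
    def test_constant_field_selects_entire_roi(self):
        vol = make_volume(np.full((8, 8, 8), 2.0))
        roi = ROI((1, 1, 1), (5, 6, 7))
        mask = threshold_percent_max(vol, roi, 0.4)
        expected = np.zeros(vol.shape, dtype=bool)
        expected[roi.slices] = True
        assert np.array_equal(mask.data, expected)

    def test_sphere_recovered_exactly_at_40_percent(self, sphere_suv):
        """Contrast 4:1, threshold 0.4 x 4 = 1.6: the mask is exactly the
        sphere's voxel set, verified by exhaustive scan."""
        vol, inside, _ = sphere_suv
        mask = threshold_percent_max(vol, full_roi(vol), 0.4)
        # independent exhaustive check: voxel in mask iff SUV >= 1.6
        for idx in np.ndindex(vol.shape):
            assert mask.data[idx] == (vol.data[idx] >= 1.6)
        assert np.array_equal(mask.data, inside)

    def test_fraction_nesting(self, sphere_suv):
        vol, _, _ = sphere_suv
        noisy = vol.with_data(vol.data + np.random.default_rng(0).normal(0, 0.2, vol.shape))
        roi = full_roi(vol)
        m15 = threshold_percent_max(noisy, roi, 0.15)
        m30 = threshold_percent_max(noisy, roi, 0.30)
        m40 = threshold_percent_max(noisy, roi, 0.40)
        assert np.all(m40.data <= m30.data)
        assert np.all(m30.data <= m15.data)

    def test_mask_confined_to_roi(self, sphere_suv):
        vol, _, _ = sphere_suv
        roi = ROI((10, 10, 10), (21, 21, 21))
        mask = threshold_percent_max(vol, roi, 0.4)
        outside = np.ones(vol.shape, dtype=bool)
        outside[roi.slices] = False
        assert not mask.data[outside].any()

    def test_all_zero_roi_warns_and_returns_empty(self):
        vol = make_volume(np.zeros((5, 5, 5)))
        with pytest.warns(UserWarning, match="empty"):
            mask = threshold_percent_max(vol, full_roi(vol), 0.4)
        assert mask.n_voxels == 0

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        vol = make_volume(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            threshold_percent_max(vol, full_roi(vol), fraction)

    def test_empty_or_out_of_bounds_roi_rejected(self):
        vol = make_volume(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            ROI((2, 2, 2), (2, 3, 3))
        with pytest.raises(ValueError):
            ROI((0, 0, 0), (5, 4, 4)).validate_within(vol.shape)


class TestThresholdFixed:
    def test_cutoff_above_max_gives_empty_mask(self, sphere_suv):
        vol, _, _ = sphere_suv
        mask = threshold_fixed(vol, full_roi(vol), 99.0)
        assert mask.n_voxels == 0

    def test_suv_2p5_isolates_hot_lesion(self, sphere_suv):
        """Lesion SUV 4, background 1, cutoff 2.5: lesion voxels only."""
        vol, inside, _ = sphere_suv
        mask = threshold_fixed(vol, full_roi(vol), 2.5)
        assert np.array_equal(mask.data, inside)

    def test_cutoff_below_min_selects_whole_roi(self, sphere_suv):
        vol, _, _ = sphere_suv
        roi = ROI((2, 2, 2), (10, 10, 10))
        mask = threshold_fixed(vol, roi, 0.5)
        expected = np.zeros(vol.shape, dtype=bool)
        expected[roi.slices] = True
        assert np.array_equal(mask.data, expected)

    def test_keeps_largest_component(self):
        data = np.zeros((12, 12, 12))
        data[1:3, 1:3, 1:3] = 5.0  # 8 voxels
        data[6:10, 6:10, 6:10] = 5.0  # 64 voxels
        vol = make_volume(data)
        mask = threshold_fixed(vol, full_roi(vol), 2.5)
        assert mask.n_voxels == 64
        assert mask.data[7, 7, 7]


class TestRegionGrow:
    def test_recovers_noiseless_sphere_with_dsc_one(self, sphere_suv):
        vol, inside, truth = sphere_suv
        seed = tuple(int(i) for i in np.argwhere(inside)[len(np.argwhere(inside)) // 2])
        result = region_grow(vol, RGParams(seed_voxel=seed, inclusion_fraction=0.5))
        assert not result.leaked
        assert np.array_equal(result.mask.data, inside)
        assert dsc_between(result.mask, truth) == 1.0

    def test_inclusion_one_with_unique_max_returns_seed_only(self):
        data = np.ones((6, 6, 6))
        data[3, 3, 3] = 7.0
        vol = make_volume(data)
        result = region_grow(vol, RGParams(seed_voxel=(3, 3, 3), inclusion_fraction=1.0))
        assert result.mask.n_voxels == 1
        assert result.mask.data[3, 3, 3]

    def test_disjoint_equal_spheres_stay_separate(self):
        data = np.ones((20, 10, 10))
        data[2:5, 4:7, 4:7] = 4.0  # sphere-ish blob A
        data[14:17, 4:7, 4:7] = 4.0  # blob B, same intensity, disconnected
        vol = make_volume(data)
        result = region_grow(vol, RGParams(seed_voxel=(3, 5, 5), inclusion_fraction=0.9))
        assert result.mask.data[3, 5, 5]
        assert not result.mask.data[14:17, 4:7, 4:7].any()

    def test_result_connected_and_contains_seed(self, sphere_suv):
        from scipy import ndimage

        vol, _, _ = sphere_suv
        noisy = vol.with_data(np.clip(
            vol.data + np.random.default_rng(1).normal(0, 0.3, vol.shape), 0.01, None))
        seed = (15, 15, 15)
        result = region_grow(noisy, RGParams(seed_voxel=seed, inclusion_fraction=0.5))
        assert result.mask.data[seed]
        _, n = ndimage.label(result.mask.data, ndimage.generate_binary_structure(3, 3))
        assert n == 1

    def test_voxel_cap_flags_leakage(self, sphere_suv):
        vol, inside, _ = sphere_suv
        seed = (15, 15, 15)
        cap = int(inside.sum()) // 2
        result = region_grow(vol, RGParams(seed_voxel=seed, inclusion_fraction=0.5, max_voxels=cap))
        assert result.leaked
        assert result.mask.n_voxels == cap
        assert result.mask.data[seed]

    def test_capped_growth_is_deterministic(self, sphere_suv):
        vol, inside, _ = sphere_suv
        params = RGParams(seed_voxel=(15, 15, 15), inclusion_fraction=0.5,
                          max_voxels=int(inside.sum()) // 2)
        a = region_grow(vol, params)
        b = region_grow(vol, params)
        assert np.array_equal(a.mask.data, b.mask.data)

    def test_zero_suv_seed_rejected(self):
        vol = make_volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="seed"):
            region_grow(vol, RGParams(seed_voxel=(1, 1, 1)))

    def test_six_connectivity_excludes_diagonal_paths(self):
        data = np.ones((5, 5, 5)) * 0.1
        data[1, 1, 1] = 4.0
        data[2, 2, 2] = 4.0  # diagonal neighbor only
        vol = make_volume(data)
        r6 = region_grow(vol, RGParams(seed_voxel=(1, 1, 1), inclusion_fraction=0.9, connectivity=6))
        r26 = region_grow(vol, RGParams(seed_voxel=(1, 1, 1), inclusion_fraction=0.9, connectivity=26))
        assert r6.mask.n_voxels == 1
        assert r26.mask.n_voxels == 2
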