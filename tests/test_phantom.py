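"""Phantom generator: exact noiseless values, determinism, rasterization
accuracy, and observer-contour simulation."""

import numpy as np
import pytest

from petgtv import (
    LesionSpec,
    ObserverPerturbation,
    PhantomSpec,
    dsc_between,
    generate_phantom,
    mask_volume_cm3,
    simulate_observer_mask,
)
from petgtv.phantom import _rasterize_sphere

from conftest import brute_force_sphere_count


def simple_spec(**overrides):
    base = dict(
        field_of_view_mm=(62.0, 62.0, 62.0),
        pet_spacing_mm=(2.0, 2.0, 2.0),
        ct_spacing_mm=(2.0, 2.0, 2.0),
        background_activity=1.0,
        lesions=[LesionSpec((31.0, 31.0, 31.0), 20.0, 4.0)],
    )
    base.update(overrides)
    return PhantomSpec(**base)


class TestGeneratePhantom:
    def test_noiseless_blur_free_values_are_exact(self, sphere_phantom):
        """Without PSF or noise every voxel is exactly background or
        contrast x background, depending only on its center position."""
        pet = sphere_phantom.pet
        inside = _rasterize_sphere(pet.shape, pet.spacing_mm, pet.origin_mm,
                                   sphere_phantom.spec.lesions[0])
        assert np.all(pet.data[inside] == 4.0)
        assert np.all(pet.data[~inside] == 1.0)

    def test_same_seed_is_bit_identical(self):
        spec = simple_spec(psf_fwhm_mm=6.0, noise_sd_fraction=0.2, rng_seed=7)
        a = generate_phantom(spec)
        b = generate_phantom(simple_spec(psf_fwhm_mm=6.0, noise_sd_fraction=0.2, rng_seed=7))
        assert np.array_equal(a.pet.data, b.pet.data)
        assert np.array_equal(a.ct.data, b.ct.data)

    def test_different_seed_changes_noise(self):
        a = generate_phantom(simple_spec(noise_sd_fraction=0.2, rng_seed=1))
        b = generate_phantom(simple_spec(noise_sd_fraction=0.2, rng_seed=2))
        assert not np.array_equal(a.pet.data, b.pet.data)

    def test_truth_mask_count_matches_brute_force_and_analytic(self, sphere_phantom):
        """The 20 mm sphere on a 2 mm grid: count equals the independent
        triple-loop rasterization and lies within 2% of the analytic volume."""
        truth = sphere_phantom.truth_masks[0]
        oracle = brute_force_sphere_count(
            truth.shape, truth.spacing_mm, truth.origin_mm, (31.0, 31.0, 31.0), 20.0
        )
        assert truth.n_voxels == oracle
        analytic = (4.0 / 3.0) * np.pi * 10.0**3 / 8.0  # voxels of 8 mm^3
        assert abs(truth.n_voxels - analytic) / analytic < 0.02

    @pytest.mark.parametrize("spacing", [2.0, 1.0, 0.5])
    def test_truth_volume_converges_to_analytic(self, spacing):
        spec = simple_spec(ct_spacing_mm=(spacing,) * 3)
        truth = generate_phantom(spec).truth_masks[0]
        analytic_cm3 = (4.0 / 3.0) * np.pi * 1.0**3  # r = 1 cm
        rel_err = abs(mask_volume_cm3(truth) - analytic_cm3) / analytic_cm3
        # voxelization error shrinks with the surface-to-volume ratio
        assert rel_err < 0.03 * spacing

    def test_lesion_floor_above_background_ceiling_when_hot(self):
        """Noiseless, blur-free: every lesion voxel exceeds every background
        voxel whenever contrast > 1."""
        pair = generate_phantom(simple_spec(lesions=[LesionSpec((31, 31, 31), 20, 1.5)]))
        pet = pair.pet
        inside = _rasterize_sphere(pet.shape, pet.spacing_mm, pet.origin_mm, pair.spec.lesions[0])
        assert pet.data[inside].min() >= pet.data[~inside].max()

    def test_ct_is_uniform_lesions_invisible(self, sphere_phantom):
        assert np.unique(sphere_phantom.ct.data).size == 1

    def test_pet_and_ct_cover_same_extent(self):
        pair = generate_phantom(
            simple_spec(pet_spacing_mm=(4.0, 4.0, 4.25), ct_spacing_mm=(0.98, 0.98, 2.0),
                        field_of_view_mm=(60.0, 60.0, 60.0),
                        lesions=[LesionSpec((30.0, 30.0, 30.0), 20.0, 4.0)])
        )
        pet_lo, pet_hi = pair.pet.physical_bounds()
        ct_lo, ct_hi = pair.ct.physical_bounds()
        assert np.all(np.abs(pet_lo - ct_lo) <= pair.pet.spacing_mm)
        assert np.all(np.abs(pet_hi - ct_hi) <= pair.pet.spacing_mm)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(lesions=[LesionSpec((5.0, 31.0, 31.0), 20.0, 4.0)]),  # pokes out of FOV
            dict(ct_spacing_mm=(0.0, 2.0, 2.0)),
            dict(pet_spacing_mm=(-1.0, 2.0, 2.0)),
            dict(background_activity=0.0),
            dict(noise_sd_fraction=-0.1),
        ],
    )
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            simple_spec(**bad)

    @pytest.mark.parametrize("param", [dict(diameter_mm=-3.0), dict(contrast_ratio=0.0)])
    def test_invalid_lesion_rejected(self, param):
        base = dict(center_mm=(31.0, 31.0, 31.0), diameter_mm=20.0, contrast_ratio=4.0)
        base.update(param)
        with pytest.raises(ValueError):
            LesionSpec(**base)


class TestSimulateObserverMask:
    def test_zero_perturbation_is_identity(self, sphere_phantom):
        truth = sphere_phantom.truth_masks[0]
        observed = simulate_observer_mask(truth, ObserverPerturbation())
        assert np.array_equal(observed.data, truth.data)
        assert dsc_between(observed, truth) == 1.0

    def test_positive_shift_dilates_to_analytic_volume(self):
        """+2 mm boundary shift on a 20 mm sphere: superset of truth with
        volume ratio close to the analytic (12/10)^3.

        Checked on a 0.5 mm grid: the discrete signed-distance shift carries
        a boundary-quantization error that shrinks with spacing (about +3.5%
        on this grid for this shift), hence the 6% band."""
        spec = PhantomSpec(
            field_of_view_mm=(62.0, 62.0, 62.0),
            ct_spacing_mm=(0.5, 0.5, 0.5),
            background_activity=1.0,
            lesions=[LesionSpec((31.0, 31.0, 31.0), 20.0, 4.0)],
        )
        truth = generate_phantom(spec).truth_masks[0]
        shifted = simulate_observer_mask(truth, ObserverPerturbation(boundary_shift_mm=2.0))
        assert np.all(shifted.data[truth.data])  # contains truth
        ratio = shifted.n_voxels / truth.n_voxels
        assert ratio == pytest.approx((12.0 / 10.0) ** 3, rel=0.06)

    def test_negative_shift_erodes(self, sphere_phantom):
        truth = sphere_phantom.truth_masks[0]
        eroded = simulate_observer_mask(truth, ObserverPerturbation(boundary_shift_mm=-2.0))
        assert eroded.n_voxels < truth.n_voxels
        assert np.all(truth.data[eroded.data])

    def test_mean_dsc_degrades_with_deformation(self, sphere_phantom):
        """Monte-Carlo over 20 seeds: mean DSC vs truth is non-increasing in
        the deformation amplitude."""
        truth = sphere_phantom.truth_masks[0]
        means = []
        for sd in (0.0, 1.0, 2.0, 4.0):
            vals = [
                dsc_between(
                    simulate_observer_mask(
                        truth, ObserverPerturbation(deformation_sd_mm=sd, rng_seed=seed)
                    ),
                    truth,
                )
                for seed in range(20)
            ]
            means.append(np.mean(vals))
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_seed_determinism(self, sphere_phantom):
        truth = sphere_phantom.truth_masks[0]
        p = ObserverPerturbation(deformation_sd_mm=2.0, rng_seed=5)
        a = simulate_observer_mask(truth, p)
        b = simulate_observer_mask(truth, p)
        assert np.array_equal(a.data, b.data)

    def test_empty_truth_rejected(self, sphere_phantom):
        truth = sphere_phantom.truth_masks[0]
        empty = type(truth).like(truth, np.zeros(truth.shape, dtype=bool))
        with pytest.raises(ValueError):
            simulate_observer_mask(empty, ObserverPerturbation())
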