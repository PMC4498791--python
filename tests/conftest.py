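import numpy as np
import pytest

from petgtv import BinaryMask, ImageVolume, LesionSpec, PhantomSpec, generate_phantom


@pytest.fixture
def sphere_phantom():
    """Noiseless, blur-free 20 mm sphere (contrast 4:1) on matched 2 mm grids.

    The sphere center (31, 31, 31) sits exactly on a voxel center so the
    rasterized voxel count is the canonical lattice count for radius 5.
    """
    spec = PhantomSpec(
        field_of_view_mm=(62.0, 62.0, 62.0),
        pet_spacing_mm=(2.0, 2.0, 2.0),
        ct_spacing_mm=(2.0, 2.0, 2.0),
        background_activity=1.0,
        lesions=[LesionSpec(center_mm=(31.0, 31.0, 31.0), diameter_mm=20.0, contrast_ratio=4.0)],
        psf_fwhm_mm=0.0,
        noise_sd_fraction=0.0,
        rng_seed=0,
    )
    return generate_phantom(spec)


def make_volume(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return ImageVolume(np.asarray(data, dtype=float), spacing, origin)


def make_mask(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return BinaryMask(np.asarray(data, dtype=bool), spacing, origin)


def brute_force_sphere_count(shape, spacing, origin, center, diameter):
    """Independent triple-loop rasterization oracle: voxel centers inside."""
    r2 = (diameter / 2.0) ** 2
    count = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                x = origin[0] + spacing[0] * i - center[0]
                y = origin[1] + spacing[1] * j - center[1]
                z = origin[2] + spacing[2] * k - center[2]
                if x * x + y * y + z * z <= r2:
                    count += 1
    return count
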