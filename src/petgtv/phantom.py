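"""IEC-style digital phantoms: spherical lesions in a uniform background.

The phantom emulates the test objects used to characterise PET quantification
and segmentation: a warm background compartment containing hot spheres at a
configurable lesion-to-background contrast ratio, degraded by a Gaussian
point-spread function (partial-volume effect) and additive Gaussian noise.
The paired CT volume is a uniform soft-tissue map on a finer anisotropic grid;
lesions are isointense on CT, so segmentation has to rely on the PET signal —
the situation that makes tracer contrast decisive for tumor delineation.

Ground-truth lesion masks are analytic spheres rasterized on the CT grid
(a voxel belongs to a sphere iff its *center* lies inside), so every
downstream overlap statistic has an exact, countable reference.

:func:`simulate_observer_mask` produces imperfect "manual" contours from a
truth mask by shifting its boundary (systematic over-/under-contouring) and
adding a smooth random deformation field (idiosyncratic observer variation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, ImageVolume

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PhantomPair",
    "ObserverPerturbation",
    "generate_phantom",
    "simulate_observer_mask",
]

#: Default grids follow common clinical PET/CT resolutions: coarse PET,
#: fine anisotropic CT.
DEFAULT_PET_SPACING_MM = (4.0, 4.0, 4.25)
DEFAULT_CT_SPACING_MM = (0.98, 0.98, 2.0)

#: Uniform soft-tissue CT number (HU) used for the phantom body.
SOFT_TISSUE_HU = 40.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class LesionSpec:
    """A spherical lesion: center (mm, LPS), diameter (mm) and
    lesion-to-background activity contrast ratio."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    contrast_ratio: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError(f"lesion diameter must be > 0, got {self.diameter_mm}")
        if self.contrast_ratio <= 0:
            raise ValueError(f"contrast ratio must be > 0, got {self.contrast_ratio}")


@dataclass
class PhantomSpec:
    """Declarative description of a phantom realization.

    Parameters
    ----------
    field_of_view_mm
        Physical extent of the phantom box along x/y/z.
    pet_spacing_mm, ct_spacing_mm
        Voxel spacings of the simulated PET and CT grids.
    background_activity
        Background activity concentration in kBq/mL.
    lesions
        Spheres placed in the background; each must lie fully inside the
        field of view.
    psf_fwhm_mm
        Isotropic Gaussian PSF full-width-at-half-maximum applied to the
        ideal PET activity (0 disables blurring).
    noise_sd_fraction
        SD of additive zero-mean Gaussian noise, as a fraction of the
        background activity (0 disables noise).
    rng_seed
        Seed for the noise generator; equal (spec, seed) pairs give
        bit-identical phantoms.
    """

    field_of_view_mm: tuple[float, float, float]
    pet_spacing_mm: tuple[float, float, float] = DEFAULT_PET_SPACING_MM
    ct_spacing_mm: tuple[float, float, float] = DEFAULT_CT_SPACING_MM
    background_activity: float = 5.0
    lesions: list[LesionSpec] = field(default_factory=list)
    psf_fwhm_mm: float = 0.0
    noise_sd_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fov = np.asarray(self.field_of_view_mm, dtype=float)
        if fov.shape != (3,) or np.any(fov <= 0):
            raise ValueError("field_of_view_mm must be a positive 3-vector")
        for name in ("pet_spacing_mm", "ct_spacing_mm"):
            sp = np.asarray(getattr(self, name), dtype=float)
            if sp.shape != (3,) or np.any(sp <= 0):
                raise ValueError(f"{name} must be a positive 3-vector")
        if self.background_activity <= 0:
            raise ValueError("background_activity must be > 0")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")
        self.lesions = [
            l if isinstance(l, LesionSpec) else LesionSpec(**l) for l in self.lesions
        ]
        for les in self.lesions:
            c = np.asarray(les.center_mm, dtype=float)
            r = les.diameter_mm / 2.0
            if np.any(c - r < 0) or np.any(c + r > fov):
                raise ValueError(
                    f"lesion at {les.center_mm} with diameter {les.diameter_mm} mm "
                    "extends outside the field of view"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["lesions"] = [LesionSpec(**l) if isinstance(l, dict) else l for l in d.get("lesions", [])]
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "field_of_view_mm": list(self.field_of_view_mm),
            "pet_spacing_mm": list(self.pet_spacing_mm),
            "ct_spacing_mm": list(self.ct_spacing_mm),
            "background_activity": self.background_activity,
            "lesions": [
                {
                    "center_mm": list(l.center_mm),
                    "diameter_mm": l.diameter_mm,
                    "contrast_ratio": l.contrast_ratio,
                }
                for l in self.lesions
            ],
            "psf_fwhm_mm": self.psf_fwhm_mm,
            "noise_sd_fraction": self.noise_sd_fraction,
            "rng_seed": self.rng_seed,
        }


@dataclass
class PhantomPair:
    """A simulated PET/CT acquisition with exact ground truth."""

    pet: ImageVolume  # activity concentration, kBq/mL, on the PET grid
    ct: ImageVolume  # CT numbers (HU), on the CT grid
    truth_masks: list[BinaryMask]  # one analytic-sphere mask per lesion, CT grid
    spec: PhantomSpec

    def __post_init__(self) -> None:
        for i, mask in enumerate(self.truth_masks):
            if mask.n_voxels == 0:
                raise ValueError(f"truth mask {i} is empty (lesion below grid resolution)")
            _, n_comp = ndimage.label(mask.data)
            if n_comp != 1:
                raise ValueError(f"truth mask {i} is not connected")


def _make_grid(fov: np.ndarray, spacing: np.ndarray) -> tuple[tuple[int, int, int], np.ndarray]:
    """Grid shape and origin so that voxels tile [0, fov] as closely as possible.

    Voxel centers start half a spacing in from the box edge; origin is the
    first voxel center.
    """
    shape = tuple(max(1, int(round(f / s))) for f, s in zip(fov, spacing))
    origin = spacing / 2.0
    return shape, origin


def _rasterize_sphere(
    shape: tuple[int, int, int], spacing: np.ndarray, origin: np.ndarray, lesion: LesionSpec
) -> np.ndarray:
    """Boolean array: voxel center within the closed sphere.

    The closed ball keeps centers that fall exactly on the surface, so a
    sphere centered on a voxel center has no boundary-lattice bias.
    """
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    cx, cy, cz = lesion.center_mm
    r2 = (lesion.diameter_mm / 2.0) ** 2
    d2 = (
        (axes[0][:, None, None] - cx) ** 2
        + (axes[1][None, :, None] - cy) ** 2
        + (axes[2][None, None, :] - cz) ** 2
    )
    return d2 <= r2


def generate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Simulate a PET/CT pair with known lesion ground truth.

    The PET volume is the ideal piecewise-constant activity map sampled at
    voxel centers (background everywhere, ``contrast_ratio x background``
    inside each sphere), convolved with the Gaussian PSF, then degraded by
    additive Gaussian noise. The CT is uniform soft tissue — lesions are
    deliberately invisible on CT. Equal (spec, seed) pairs give bit-identical
    output.
    """
    fov = np.asarray(spec.field_of_view_mm, dtype=float)
    pet_spacing = np.asarray(spec.pet_spacing_mm, dtype=float)
    ct_spacing = np.asarray(spec.ct_spacing_mm, dtype=float)

    pet_shape, pet_origin = _make_grid(fov, pet_spacing)
    ct_shape, ct_origin = _make_grid(fov, ct_spacing)

    pet_data = np.full(pet_shape, float(spec.background_activity))
    for les in spec.lesions:
        inside = _rasterize_sphere(pet_shape, pet_spacing, pet_origin, les)
        lesion_activity = les.contrast_ratio * spec.background_activity
        pet_data = np.where(inside, np.maximum(pet_data, lesion_activity), pet_data)

    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm * _FWHM_TO_SIGMA / pet_spacing
        pet_data = ndimage.gaussian_filter(pet_data, sigma=sigma_vox, mode="nearest")

    if spec.noise_sd_fraction > 0:
        rng = np.random.default_rng(spec.rng_seed)
        pet_data = pet_data + rng.normal(
            0.0, spec.noise_sd_fraction * spec.background_activity, size=pet_shape
        )

    pet = ImageVolume(pet_data, pet_spacing, pet_origin)
    ct = ImageVolume(np.full(ct_shape, SOFT_TISSUE_HU), ct_spacing, ct_origin)
    truth_masks = [
        BinaryMask.like(ct, _rasterize_sphere(ct_shape, ct_spacing, ct_origin, les))
        for les in spec.lesions
    ]
    return PhantomPair(pet=pet, ct=ct, truth_masks=truth_masks, spec=spec)


@dataclass
class ObserverPerturbation:
    """Parameters of a simulated manual contour.

    ``boundary_shift_mm`` moves the whole contour surface outward (positive,
    over-contouring) or inward (negative); ``deformation_sd_mm`` adds a smooth
    zero-mean random field to the signed distance before re-thresholding, so
    the boundary wobbles locally. ``correlation_length_mm`` sets the spatial
    scale of that wobble.
    """

    boundary_shift_mm: float = 0.0
    deformation_sd_mm: float = 0.0
    correlation_length_mm: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.deformation_sd_mm < 0:
            raise ValueError("deformation_sd_mm must be >= 0")
        if self.correlation_length_mm <= 0:
            raise ValueError("correlation_length_mm must be > 0")


def signed_distance_mm(mask: BinaryMask) -> np.ndarray:
    """Signed Euclidean distance to the mask surface, negative inside (mm).

    The voxel EDT measures center-to-center distances, which overestimate
    the distance to the continuous boundary (lying between the two nearest
    centers) by about half a voxel; that bias is subtracted, with the
    magnitude floored at a quarter voxel so the sign still encodes
    membership exactly.
    """
    inside = mask.data
    spacing = np.asarray(mask.spacing_mm)
    half = 0.5 * float(spacing.mean())
    floor = 0.25 * float(spacing.min())
    d_out = ndimage.distance_transform_edt(~inside, sampling=spacing)
    d_in = ndimage.distance_transform_edt(inside, sampling=spacing)
    sd_out = np.maximum(d_out - half, floor)
    sd_in = np.maximum(d_in - half, floor)
    return np.where(inside, -sd_in, sd_out)


def simulate_observer_mask(truth: BinaryMask, perturb: ObserverPerturbation) -> BinaryMask:
    """Perturb a truth mask into an imperfect observer contour.

    The new contour is the zero level set of
    ``signed_distance(truth) - boundary_shift - smooth_field``; with both
    parameters zero it is the identity. Seed-deterministic.
    """
    if truth.n_voxels == 0:
        raise ValueError("cannot perturb an empty truth mask")
    if perturb.boundary_shift_mm == 0.0 and perturb.deformation_sd_mm == 0.0:
        return BinaryMask.like(truth, truth.data.copy())

    sd = signed_distance_mm(truth)
    level = perturb.boundary_shift_mm
    if perturb.deformation_sd_mm > 0:
        rng = np.random.default_rng(perturb.rng_seed)
        white = rng.standard_normal(truth.shape)
        sigma_vox = perturb.correlation_length_mm / np.asarray(truth.spacing_mm)
        smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
        sd_smooth = smooth.std()
        if sd_smooth > 0:
            smooth = smooth * (perturb.deformation_sd_mm / sd_smooth)
        level = level + smooth
    return BinaryMask.like(truth, sd <= level)
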