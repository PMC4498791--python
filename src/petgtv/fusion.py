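"""PET/CT grid fusion by stored physical coordinates.

The PET volume is resampled onto the CT grid using the physical metadata
(spacing, origin, direction) carried in the image headers — no registration
optimization is performed, mirroring scanner-side hardware alignment. Pairs
whose physical extents do not overlap sufficiently are flagged for exclusion,
the quantitative stand-in for visually "conspicuous" misalignment (head
movement between acquisitions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .volume import BinaryMask, ImageVolume

__all__ = [
    "AlignmentReport",
    "DEFAULT_MIN_OVERLAP",
    "resample_to_grid",
    "resample_mask_to_grid",
    "check_alignment",
]

#: Minimum fraction of the CT extent that the PET extent must cover for a
#: pair to count as aligned.
DEFAULT_MIN_OVERLAP = 0.95


@dataclass
class AlignmentReport:
    overlap_fraction: float  # fraction of the CT physical extent covered by PET
    aligned: bool
    min_overlap: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0 + 1e-12:
            raise ValueError("overlap_fraction must lie in [0, 1]")


def resample_to_grid(moving: ImageVolume, target: ImageVolume) -> ImageVolume:
    """Trilinearly interpolate ``moving`` at every voxel center of ``target``.

    Positions outside the moving volume's extent are filled with 0 (activity
    outside the field of view is unknown; zero keeps SUV thresholds
    conservative). The result carries the target's grid metadata.
    """
    resampled = sitk.Resample(
        moving.to_sitk(),
        target.to_sitk(),
        sitk.Transform(),  # identity: alignment comes from physical metadata
        sitk.sitkLinear,
        0.0,
        sitk.sitkFloat64,
    )
    return ImageVolume.from_sitk(resampled)


def resample_mask_to_grid(mask: BinaryMask, target: ImageVolume | BinaryMask) -> BinaryMask:
    """Nearest-neighbor resampling for masks (keeps them binary)."""
    target_vol = ImageVolume(
        np.zeros(target.shape), target.spacing_mm, target.origin_mm, target.direction
    )
    resampled = sitk.Resample(
        mask.to_sitk(),
        target_vol.to_sitk(),
        sitk.Transform(),
        sitk.sitkNearestNeighbor,
        0,
    )
    vol = ImageVolume.from_sitk(resampled)
    return BinaryMask.like(vol, vol.data > 0)


def check_alignment(
    pet: ImageVolume, ct: ImageVolume, min_overlap: float = DEFAULT_MIN_OVERLAP
) -> AlignmentReport:
    """Fraction of the CT physical bounding box covered by the PET box.

    Axis-aligned physical extents are intersected; the pair is ``aligned``
    when the intersection covers at least ``min_overlap`` of the CT box.
    """
    pet_lo, pet_hi = pet.physical_bounds()
    ct_lo, ct_hi = ct.physical_bounds()
    inter_lo = np.maximum(pet_lo, ct_lo)
    inter_hi = np.minimum(pet_hi, ct_hi)
    inter_extent = np.clip(inter_hi - inter_lo, 0.0, None)
    ct_volume = float(np.prod(ct_hi - ct_lo))
    if ct_volume <= 0:
        raise ValueError("CT volume has degenerate physical extent")
    frac = float(np.prod(inter_extent) / ct_volume)
    frac = min(frac, 1.0)
    return AlignmentReport(overlap_fraction=frac, aligned=frac >= min_overlap, min_overlap=min_overlap)
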