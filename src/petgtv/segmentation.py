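"""GTV delineation on SUV volumes.

Three semi-automatic families are provided, the ones commonly validated for
PET target definition:

* percent-of-local-maximum thresholding (SUV_15%, SUV_30%, SUV_40%): the
  local maximum is taken over an explicit user ROI box, and the mask is the
  connected component (26-connectivity) containing the maximum voxel;
* fixed-SUV thresholding (classically SUV >= 2.5), keeping the largest
  connected component;
* seeded region growing: breadth-first growth from a seed voxel, admitting
  neighbors whose SUV is at least ``inclusion_fraction`` times the seed SUV,
  with a voxel cap that flags suspected leakage into adjacent uptake.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, ImageVolume

__all__ = [
    "ROI",
    "RGParams",
    "RegionGrowResult",
    "threshold_percent_max",
    "threshold_fixed",
    "region_grow",
]

_STRUCT_26 = ndimage.generate_binary_structure(3, 3)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class ROI:
    """Axis-aligned box in voxel indices: inclusive lower, exclusive upper."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lower, int), np.asarray(self.upper, int)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("ROI bounds must be 3-vectors of voxel indices")
        if np.any(lo < 0):
            raise ValueError("ROI lower bound must be >= 0")
        if np.any(hi <= lo):
            raise ValueError("ROI must be nonempty (upper > lower per axis)")

    def validate_within(self, shape: tuple[int, int, int]) -> None:
        if np.any(np.asarray(self.upper) > np.asarray(shape)):
            raise ValueError(f"ROI {self.lower}..{self.upper} exceeds volume shape {shape}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, u) for l, u in zip(self.lower, self.upper))  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(np.asarray(self.upper) - np.asarray(self.lower)))

    @classmethod
    def around_mask(cls, mask: BinaryMask, pad_mm: float = 10.0) -> "ROI":
        """Bounding box of a mask, padded by ``pad_mm`` and clipped to the grid."""
        idx = np.argwhere(mask.data)
        if idx.size == 0:
            raise ValueError("cannot build an ROI around an empty mask")
        pad_vox = np.ceil(pad_mm / mask.spacing_mm).astype(int)
        lo = np.maximum(idx.min(axis=0) - pad_vox, 0)
        hi = np.minimum(idx.max(axis=0) + 1 + pad_vox, np.asarray(mask.shape))
        return cls(tuple(lo), tuple(hi))


@dataclass
class RGParams:
    """Region-growing parameters.

    A neighbor joins the region when ``SUV >= inclusion_fraction * SUV(seed)``.
    Growth halts at ``max_voxels``, in which case the result is flagged as
    suspected leakage.
    """

    seed_voxel: tuple[int, int, int]
    inclusion_fraction: float = 0.5
    connectivity: int = 26
    max_voxels: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0.0 < self.inclusion_fraction <= 1.0:
            raise ValueError("inclusion_fraction must lie in (0, 1]")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.max_voxels < 1:
            raise ValueError("max_voxels must be >= 1")


@dataclass
class RegionGrowResult:
    mask: BinaryMask
    leaked: bool  # growth hit the voxel cap — leakage suspected


def _component_containing(candidate: np.ndarray, index: tuple[int, ...], structure: np.ndarray) -> np.ndarray:
    labels, _ = ndimage.label(candidate, structure=structure)
    lab = labels[index]
    assert lab != 0, "index must lie inside the candidate set"
    return labels == lab


def threshold_percent_max(suv: ImageVolume, roi: ROI, fraction: float) -> BinaryMask:
    """Mask of ROI voxels with SUV >= fraction x (max SUV in ROI).

    The raw threshold mask is reduced to the 26-connected component containing
    the maximum voxel, discarding disconnected speckle a human contourer would
    ignore. An all-nonpositive ROI yields an empty mask with a warning.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    roi.validate_within(suv.shape)
    sub = np.asarray(suv.data)[roi.slices]
    m = float(sub.max())
    out = np.zeros(suv.shape, dtype=bool)
    if m <= 0:
        warnings.warn("ROI maximum SUV is <= 0; returning an empty mask", stacklevel=2)
        return BinaryMask.like(suv, out)
    candidate = sub >= fraction * m
    argmax = np.unravel_index(int(np.argmax(sub)), sub.shape)
    out[roi.slices] = _component_containing(candidate, argmax, _STRUCT_26)
    return BinaryMask.like(suv, out)


def threshold_fixed(suv: ImageVolume, roi: ROI, cutoff: float) -> BinaryMask:
    """Mask of ROI voxels with SUV >= cutoff, largest 26-connected component.

    An empty result (cutoff above the ROI maximum) is allowed.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    roi.validate_within(suv.shape)
    sub = np.asarray(suv.data)[roi.slices]
    candidate = sub >= cutoff
    out = np.zeros(suv.shape, dtype=bool)
    if candidate.any():
        labels, n = ndimage.label(candidate, structure=_STRUCT_26)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        largest = int(np.argmax(sizes)) + 1
        out[roi.slices] = labels == largest
    return BinaryMask.like(suv, out)


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    struct = _STRUCT_26 if connectivity == 26 else _STRUCT_6
    offsets = np.argwhere(struct) - 1
    return offsets[np.any(offsets != 0, axis=1)]


def region_grow(suv: ImageVolume, params: RGParams) -> RegionGrowResult:
    """Breadth-first region growing from a seed voxel.

    The admitted set is ``SUV >= inclusion_fraction * SUV(seed)`` restricted to
    the connected component of the seed; when that component exceeds
    ``max_voxels``, growth stops at the cap (in breadth-first order, a fixed
    deterministic neighbor ordering) and the result is flagged ``leaked``.
    """
    data = np.asarray(suv.data)
    seed = tuple(int(i) for i in params.seed_voxel)
    if any(i < 0 or i >= n for i, n in zip(seed, data.shape)):
        raise ValueError(f"seed {seed} outside volume of shape {data.shape}")
    seed_suv = float(data[seed])
    if seed_suv <= 0:
        raise ValueError("seed voxel has nonpositive SUV; choose a seed inside uptake")

    threshold = params.inclusion_fraction * seed_suv
    structure = _STRUCT_26 if params.connectivity == 26 else _STRUCT_6
    candidate = data >= threshold
    component = _component_containing(candidate, seed, structure)
    size = int(component.sum())
    if size <= params.max_voxels:
        return RegionGrowResult(mask=BinaryMask.like(suv, component), leaked=False)

    # capped growth: explicit BFS, stopping once max_voxels are admitted
    offsets = _neighbor_offsets(params.connectivity)
    grown = np.zeros(data.shape, dtype=bool)
    grown[seed] = True
    count = 1
    queue: deque[tuple[int, int, int]] = deque([seed])
    shape = data.shape
    while queue and count < params.max_voxels:
        current = queue.popleft()
        for off in offsets:
            ni, nj, nk = current[0] + off[0], current[1] + off[1], current[2] + off[2]
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                continue
            if grown[ni, nj, nk] or not candidate[ni, nj, nk]:
                continue
            grown[ni, nj, nk] = True
            queue.append((ni, nj, nk))
            count += 1
            if count >= params.max_voxels:
                break
    return RegionGrowResult(mask=BinaryMask.like(suv, grown), leaked=True)
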