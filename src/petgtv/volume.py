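"""Image-volume and binary-mask containers with physical-grid metadata.

Conventions used throughout the package:

* arrays are indexed ``data[i, j, k]`` where axis 0/1/2 correspond to the
  physical x/y/z axes;
* world coordinates are LPS (the native SimpleITK/DICOM convention);
* voxel indices are 0-based and address voxel *centers*:
  ``position = origin + direction @ (spacing * index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

__all__ = ["ImageVolume", "BinaryMask", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


def _identity_direction() -> np.ndarray:
    return np.eye(3)


def _validate_grid(spacing: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> None:
    if spacing.shape != (3,) or origin.shape != (3,):
        raise ValueError("spacing_mm and origin_mm must be 3-vectors")
    if np.any(spacing <= 0):
        raise ValueError(f"voxel spacing must be positive, got {spacing}")
    if direction.shape != (3, 3):
        raise ValueError("direction must be a 3x3 matrix")
    if not np.allclose(direction @ direction.T, np.eye(3), atol=1e-6):
        raise ValueError("direction matrix must be orthonormal")


@dataclass
class ImageVolume:
    """3-D scalar grid (activity, SUV or CT numbers) with physical metadata."""

    data: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    direction: np.ndarray = field(default_factory=_identity_direction)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        _validate_grid(self.spacing_mm, self.origin_mm, self.direction)

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Physical (LPS, mm) position of voxel-center ``index`` (may be fractional)."""
        index = np.asarray(index, dtype=float)
        return self.origin_mm + (self.direction @ (self.spacing_mm * index).T).T

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of all voxel centers as three broadcastable grids."""
        axes = [
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        if not np.allclose(self.direction, np.eye(3)):
            # general (oblique) case: build full coordinate arrays
            ii, jj, kk = np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij")
            idx = np.stack([ii, jj, kk], axis=-1).astype(float)
            pos = self.origin_mm + np.einsum("ab,...b->...a", self.direction, idx * self.spacing_mm)
            return pos[..., 0], pos[..., 1], pos[..., 2]
        return (
            axes[0][:, None, None],
            axes[1][None, :, None],
            axes[2][None, None, :],
        )

    def physical_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (lower, upper) of the voxel *extent* in mm.

        The extent pads each voxel center by half a spacing so the box covers
        the full sensitive volume, not just the center lattice.
        """
        n = np.array(self.shape)
        corners = []
        for ci in (-0.5, n[0] - 0.5):
            for cj in (-0.5, n[1] - 0.5):
                for ck in (-0.5, n[2] - 0.5):
                    corners.append(self.index_to_physical(np.array([ci, cj, ck])))
        corners = np.array(corners)
        return corners.min(axis=0), corners.max(axis=0)

    def same_grid(self, other: "ImageVolume | BinaryMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    # -- SimpleITK / NIfTI bridge ------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T))  # (x,y,z)->(z,y,x)
        img.SetSpacing(tuple(self.spacing_mm))
        img.SetOrigin(tuple(self.origin_mm))
        img.SetDirection(tuple(self.direction.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        data = sitk.GetArrayFromImage(img).T  # (z,y,x)->(x,y,z)
        return cls(
            data=data,
            spacing_mm=np.array(img.GetSpacing()),
            origin_mm=np.array(img.GetOrigin()),
            direction=np.array(img.GetDirection()).reshape(3, 3),
        )

    def save_nifti(self, path: str) -> None:
        sitk.WriteImage(self.to_sitk(), str(path))

    @classmethod
    def load_nifti(cls, path: str) -> "ImageVolume":
        return cls.from_sitk(sitk.ReadImage(str(path)))

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=data)


@dataclass
class BinaryMask:
    """Boolean 3-D grid (a contour / GTV) on a stated reference grid."""

    data: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    direction: np.ndarray = field(default_factory=_identity_direction)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        _validate_grid(self.spacing_mm, self.origin_mm, self.direction)

    shape = ImageVolume.shape
    voxel_volume_mm3 = ImageVolume.voxel_volume_mm3
    index_to_physical = ImageVolume.index_to_physical
    physical_bounds = ImageVolume.physical_bounds
    same_grid = ImageVolume.same_grid

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @classmethod
    def like(cls, grid: "ImageVolume | BinaryMask", data: np.ndarray) -> "BinaryMask":
        """A mask sharing ``grid``'s metadata."""
        return cls(
            data=data,
            spacing_mm=grid.spacing_mm.copy(),
            origin_mm=grid.origin_mm.copy(),
            direction=grid.direction.copy(),
        )

    def to_sitk(self) -> sitk.Image:
        vol = ImageVolume(
            self.data.astype(np.uint8), self.spacing_mm, self.origin_mm, self.direction
        )
        return vol.to_sitk()

    def save_nifti(self, path: str) -> None:
        sitk.WriteImage(self.to_sitk(), str(path))

    @classmethod
    def load_nifti(cls, path: str) -> "BinaryMask":
        vol = ImageVolume.load_nifti(path)
        return cls.like(vol, vol.data > 0)
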