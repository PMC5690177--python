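"""Core image containers shared by the whole pipeline.

Patient coordinates follow the DICOM LPS convention: x increases toward the
patient's left (the lateral beam axis in whole-brain treatments), y toward
posterior, z toward superior.  Voxel arrays are indexed ``(i, j, k)`` along
those same axes, so ``voxels[i, j, k]`` sits at
``origin + (i * sx, j * sy, k * sz)`` in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGeometry", "CTVolume", "BinaryMask"]


@dataclass(frozen=True)
class ImageGeometry:
    """Physical placement of a voxel grid: spacing and origin in mm, plus the
    orientation of the grid axes in patient coordinates (rows of ``axes``)."""

    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )

    def __post_init__(self) -> None:
        sp = np.asarray(self.spacing_mm, dtype=float)
        if sp.shape != (3,) or not np.all(sp > 0):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        ax = np.asarray(self.axes, dtype=float)
        if ax.shape != (3, 3) or not np.allclose(ax @ ax.T, np.eye(3), atol=1e-6):
            raise ValueError("axes must be a 3x3 orthonormal matrix")
        if not np.all(np.isfinite(np.asarray(self.origin_mm, dtype=float))):
            raise ValueError("origin must be finite")

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.spacing_mm, dtype=float)

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.origin_mm, dtype=float)

    @property
    def axes_matrix(self) -> np.ndarray:
        return np.asarray(self.axes, dtype=float)

    def is_axis_aligned(self) -> bool:
        return np.allclose(self.axes_matrix, np.eye(3), atol=1e-6)

    def indices_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (n, 3) to patient coordinates in mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return self.origin + (ijk * self.spacing) @ self.axes_matrix

    def mm_to_indices(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return ((xyz - self.origin) @ self.axes_matrix.T) / self.spacing

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def _check_grid(voxels: np.ndarray) -> None:
    if voxels.ndim != 3:
        raise ValueError(f"expected a 3D grid, got shape {voxels.shape}")
    if voxels.size == 0:
        raise ValueError("empty grid")


@dataclass
class CTVolume:
    """A CT scan: a 3D grid of Hounsfield units with physical geometry."""

    voxels: np.ndarray
    geometry: ImageGeometry

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        _check_grid(self.voxels)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def spacing(self) -> np.ndarray:
        return self.geometry.spacing

    @property
    def origin(self) -> np.ndarray:
        return self.geometry.origin

    def bounding_box_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Corners of the voxel-center bounding box in patient mm."""
        hi = np.asarray(self.shape) - 1.0
        corners = self.geometry.indices_to_mm(np.array([[0.0, 0.0, 0.0], hi]))
        return corners.min(axis=0), corners.max(axis=0)


@dataclass
class BinaryMask:
    """A boolean grid sharing a CTVolume's geometry; one per structure."""

    voxels: np.ndarray
    geometry: ImageGeometry

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        _check_grid(self.voxels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def spacing(self) -> np.ndarray:
        return self.geometry.spacing

    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * self.geometry.voxel_volume_mm3

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def centroid_mm(self) -> np.ndarray:
        if self.is_empty():
            raise ValueError("centroid of an empty mask is undefined")
        ijk = np.argwhere(self.voxels)
        return self.geometry.indices_to_mm(ijk).mean(axis=0)

    def same_grid_as(self, other: "BinaryMask | CTVolume") -> bool:
        return self.shape == other.shape and self.geometry == other.geometry
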