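"""Millimetre-calibrated binary morphology.

Structuring elements are Euclidean balls specified in mm, realised through the
exact Euclidean distance transform so behaviour is invariant to voxel spacing
(including anisotropic grids).  ``erode(mask, r)`` keeps voxels whose distance
to the background exceeds ``r``; ``dilate`` is its dual.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# 26-connectivity is the package-wide default for connected components.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


def erode_mm(mask: np.ndarray, radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    if radius_mm <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask, sampling=spacing)
    return dist > radius_mm


def dilate_mm(mask: np.ndarray, radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    if radius_mm <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return mask | (dist <= radius_mm)


def close_mm(mask: np.ndarray, radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    return erode_mm(dilate_mm(mask, radius_mm, spacing), radius_mm, spacing)


def open_mm(mask: np.ndarray, radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    return dilate_mm(erode_mm(mask, radius_mm, spacing), radius_mm, spacing)


def connected_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """26-connected labelling."""
    labels, n = ndimage.label(mask, structure=CONNECTIVITY_26)
    return labels, n


def largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = connected_components(mask)
    if n == 0:
        raise ValueError("mask has no connected component")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Face-connected boundary: mask voxels with at least one 6-neighbour outside."""
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~interior
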