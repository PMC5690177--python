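"""Segmentation agreement metrics: Dice, mean surface distance, Hausdorff.

Surface distances are computed between boundary-voxel centres in millimetres.
The mean is symmetrised (all directed distances from both surfaces pooled);
the Hausdorff distance is the maximum over both directions, so both are
symmetric in their arguments and ``hausdorff >= mean`` always holds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._morphology import boundary_voxels
from .core import BinaryMask
from .dicom_io import StructureSet

__all__ = ["MetricReport", "dice", "jaccard", "surface_distances", "compare_structure_sets"]


def _check_shared_grid(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape or a.geometry != b.geometry:
        raise ValueError("masks must share one grid geometry")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Overlap 2|A∩B| / (|A|+|B|): 0 = disjoint, 1 = identical."""
    _check_shared_grid(a, b)
    na, nb = int(a.voxels.sum()), int(b.voxels.sum())
    if na == 0 and nb == 0:
        raise ValueError("Dice of two empty masks is undefined")
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """Convenience alias: intersection over union."""
    d = dice(a, b)
    return d / (2.0 - d)


def _boundary_points_mm(mask: BinaryMask) -> np.ndarray:
    ijk = np.argwhere(boundary_voxels(mask.voxels))
    return mask.geometry.indices_to_mm(ijk)


def surface_distances(a: BinaryMask, b: BinaryMask) -> tuple[float, float]:
    """(mean_mm, hausdorff_mm) between the two mask surfaces.

    Directed distances run from every boundary-voxel centre of one mask to the
    nearest boundary-voxel centre of the other; both directions are pooled for
    the mean and maximised for the Hausdorff distance.
    """
    _check_shared_grid(a, b)
    if a.is_empty() or b.is_empty():
        raise ValueError("surface distances need two nonempty masks")
    pa, pb = _boundary_points_mm(a), _boundary_points_mm(b)
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    mean = float(np.concatenate([d_ab, d_ba]).mean())
    hausdorff = float(max(d_ab.max(), d_ba.max()))
    return mean, hausdorff


@dataclass
class MetricReport:
    """Per-structure agreement between two segmentations of one patient."""

    per_structure: dict[str, dict[str, float]]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.per_structure, indent=2))
        return path

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["structure,dice,mean_surface_distance_mm,hausdorff_mm"]
        for name, row in self.per_structure.items():
            lines.append(
                f"{name},{row['dice']:.6f},"
                f"{row['mean_surface_distance_mm']:.6f},{row['hausdorff_mm']:.6f}")
        path.write_text("\n".join(lines) + "\n")
        return path


def compare_structure_sets(test: StructureSet, reference: StructureSet,
                           structures: list[str] | None = None) -> MetricReport:
    """Evaluate every structure present in both sets (or the named subset)."""
    names = structures or [n for n in test.names() if n in reference]
    if not names:
        raise ValueError("no common structures to compare")
    rows = {}
    for name in names:
        d = dice(test[name], reference[name])
        mean, hd = surface_distances(test[name], reference[name])
        rows[name] = {
            "dice": d,
            "mean_surface_distance_mm": mean,
            "hausdorff_mm": hd,
        }
    return MetricReport(rows)
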