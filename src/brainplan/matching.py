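"""Anatomy-similarity retrieval over a database of prior whole-brain cases.

A patient's brain and eye segmentations are turned into surface point clouds,
the posterior/superior brain surface is discarded (an open lateral field
covers it; only the brain-eye region shaped by the MLC must match), clouds are
aligned with a translations-only iterative-closest-point step, and each
database case is scored with a direction-selective RMS distance:

    score = sqrt( (1/N) * sum_i [ (y_i - closest(p_i)_y)^2 + (z_i - closest(p_i)_z)^2 ] )

where ``closest(p_i)`` is the full-3D nearest database point to patient point
``p_i``.  Only the anterior-posterior (y) and superior-inferior (z) residual
components enter the sum: with lateral opposed beams, left-right (x)
differences barely move the dose, while y/z differences cross the MLC-shaped
field edge.  Squaring penalises a large local mismatch more than a small
uniform one, which is what drives dose errors.

Lower scores mean better matches; a database case identical to the patient
scores exactly 0 after alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._morphology import boundary_voxels
from .core import BinaryMask

__all__ = [
    "SurfaceCloud",
    "CropPlane",
    "MatchResult",
    "mask_to_surface",
    "crop_for_matching",
    "icp_align",
    "score_surfaces",
    "match_score",
    "CaseDatabase",
    "rank_database",
]

DEFAULT_MAX_POINTS = 2000
DEFAULT_DECIMATION_SEED = 20150908


@dataclass
class SurfaceCloud:
    """Labelled surface points in patient mm (x left-right, y ant-post, z sup-inf)."""

    points: np.ndarray  # (n, 3) float
    labels: np.ndarray  # (n,) str

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.points.shape[1] != 3 or len(self.labels) != len(self.points):
            raise ValueError("points must be (n, 3) with one label per point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("surface points must be finite")

    def __len__(self) -> int:
        return len(self.points)

    def translated(self, t: np.ndarray) -> "SurfaceCloud":
        return SurfaceCloud(self.points + np.asarray(t, dtype=float), self.labels)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @staticmethod
    def concatenate(clouds: list["SurfaceCloud"]) -> "SurfaceCloud":
        return SurfaceCloud(
            np.vstack([c.points for c in clouds]),
            np.concatenate([c.labels for c in clouds]),
        )


@dataclass(frozen=True)
class CropPlane:
    """Plane discarding posterior/superior brain surface before matching.

    The normal lies in the sagittal (y-z) plane, tilted ``tilt_deg`` from +z
    toward -y — from the nape toward the forehead.  Points on the side of the
    plane containing the eyes are kept.
    """

    point_mm: tuple[float, float, float]
    tilt_deg: float = 15.0

    @property
    def normal(self) -> np.ndarray:
        t = np.deg2rad(self.tilt_deg)
        return np.array([0.0, -np.sin(t), np.cos(t)])

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - np.asarray(self.point_mm)) @ self.normal


def mask_to_surface(mask: BinaryMask, max_points: int | None = None,
                    label: str = "surface",
                    seed: int = DEFAULT_DECIMATION_SEED) -> SurfaceCloud:
    """Boundary-voxel centres in mm, uniformly decimated to ``max_points``."""
    if mask.is_empty():
        raise ValueError("cannot extract a surface from an empty mask")
    ijk = np.argwhere(boundary_voxels(mask.voxels))
    pts = mask.geometry.indices_to_mm(ijk)
    if max_points is not None and len(pts) > max_points:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(pts), size=max_points, replace=False)
        pts = pts[np.sort(keep)]
    return SurfaceCloud(pts, np.full(len(pts), label))


def default_crop_plane(eye_clouds: list[SurfaceCloud], tilt_deg: float = 15.0) -> CropPlane:
    """Plane through the superior pole of the eye globes."""
    pts = np.vstack([c.points for c in eye_clouds])
    top = pts[pts[:, 2].argmax()]
    return CropPlane(point_mm=tuple(top), tilt_deg=tilt_deg)


def crop_for_matching(structures: dict[str, BinaryMask],
                      plane: CropPlane | None = None,
                      tilt_deg: float = 15.0,
                      max_points: int = DEFAULT_MAX_POINTS,
                      seed: int = DEFAULT_DECIMATION_SEED) -> SurfaceCloud:
    """Surface cloud for matching: cropped brain plus both full eye surfaces.

    ``structures`` must contain brain, eye_L and eye_R masks.  Brain points on
    the non-eye side of the plane are discarded.
    """
    for name in ("brain", "eye_L", "eye_R"):
        if name not in structures or structures[name].is_empty():
            raise ValueError(f"matching requires a nonempty {name!r} mask")
    eye_clouds = [
        mask_to_surface(structures[n], max_points, label=n, seed=seed)
        for n in ("eye_L", "eye_R")
    ]
    brain_cloud = mask_to_surface(structures["brain"], max_points, label="brain", seed=seed)
    if plane is None:
        plane = default_crop_plane(eye_clouds, tilt_deg)
    eye_centroid = np.vstack([c.points for c in eye_clouds]).mean(axis=0)
    keep_sign = np.sign(plane.signed_distance(eye_centroid)[0]) or -1.0
    keep = plane.signed_distance(brain_cloud.points) * keep_sign >= 0
    if not keep.any():
        raise ValueError("crop plane discards the entire brain surface")
    cropped_brain = SurfaceCloud(brain_cloud.points[keep], brain_cloud.labels[keep])
    return SurfaceCloud.concatenate([cropped_brain] + eye_clouds)


def icp_align(moving: SurfaceCloud, fixed: SurfaceCloud,
              max_iter: int = 100, tol_mm: float = 1e-3) -> np.ndarray:
    """Translations-only ICP: returns t such that moving + t ~ fixed.

    Starts from the centroid difference, then alternates nearest-neighbour
    assignment with a mean-residual translation update until the update falls
    below ``tol_mm``.
    """
    if len(moving) == 0 or len(fixed) == 0:
        raise ValueError("ICP needs two nonempty clouds")
    tree = cKDTree(fixed.points)
    t = fixed.centroid() - moving.centroid()
    for _ in range(max_iter):
        _, nn = tree.query(moving.points + t)
        update = (fixed.points[nn] - (moving.points + t)).mean(axis=0)
        t = t + update
        if np.linalg.norm(update) < tol_mm:
            break
    return t


def score_surfaces(patient: SurfaceCloud, database_case: SurfaceCloud) -> float:
    """Direction-selective RMS score of already-aligned clouds.

    For each patient point the full-3D nearest database point is found; only
    the y and z components of the residual enter the root-mean-square.  The
    sum runs one way, over the patient's points.
    """
    if len(patient) == 0 or len(database_case) == 0:
        raise ValueError("cannot score an empty cloud")
    _, nn = cKDTree(database_case.points).query(patient.points)
    resid = patient.points - database_case.points[nn]
    return float(np.sqrt(np.mean(resid[:, 1] ** 2 + resid[:, 2] ** 2)))


def match_score(patient: SurfaceCloud, database_case: SurfaceCloud,
                max_iter: int = 100, tol_mm: float = 1e-3) -> tuple[float, np.ndarray]:
    """ICP-align the patient onto the database case, then score.
    Returns (score_mm, translation)."""
    t = icp_align(patient, database_case, max_iter=max_iter, tol_mm=tol_mm)
    score = score_surfaces(patient.translated(t), database_case)
    return score, t


@dataclass
class MatchResult:
    case_id: str
    translation_mm: np.ndarray
    score: float
    n_points: int
    plan_path: str | None = None

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "translation_mm": [float(v) for v in self.translation_mm],
            "score": self.score,
            "n_points": self.n_points,
            "plan_path": self.plan_path,
        }


@dataclass
class CaseDatabase:
    """Precomputed cropped surface clouds plus plan references.

    Only the structure-derived point clouds and the plan files are kept — CT
    data never enters the index, which keeps it small and the search fast.
    """

    cases: dict[str, SurfaceCloud] = field(default_factory=dict)
    plan_paths: dict[str, str] = field(default_factory=dict)

    def add_case(self, case_id: str, cloud: SurfaceCloud,
                 plan_path: str | None = None) -> None:
        if case_id in self.cases:
            raise ValueError(f"duplicate case id {case_id!r}")
        self.cases[case_id] = cloud
        if plan_path is not None:
            self.plan_paths[case_id] = str(plan_path)

    def __len__(self) -> int:
        return len(self.cases)

    def subset(self, case_ids: list[str]) -> "CaseDatabase":
        return CaseDatabase(
            cases={c: self.cases[c] for c in case_ids},
            plan_paths={c: self.plan_paths[c] for c in case_ids if c in self.plan_paths},
        )

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"cases": []}
        for case_id, cloud in self.cases.items():
            np.save(directory / f"{case_id}_points.npy", cloud.points)
            (directory / f"{case_id}_labels.json").write_text(
                json.dumps([str(l) for l in cloud.labels]))
            manifest["cases"].append({
                "case_id": case_id,
                "points": f"{case_id}_points.npy",
                "labels": f"{case_id}_labels.json",
                "plan": self.plan_paths.get(case_id),
            })
        path = directory / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
        return path

    @classmethod
    def load(cls, directory: str | Path) -> "CaseDatabase":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        db = cls()
        for entry in manifest["cases"]:
            pts = np.load(directory / entry["points"])
            labels = np.asarray(json.loads((directory / entry["labels"]).read_text()))
            db.add_case(entry["case_id"], SurfaceCloud(pts, labels), entry.get("plan"))
        return db


def rank_database(patient: SurfaceCloud, db: CaseDatabase,
                  max_iter: int = 100, tol_mm: float = 1e-3) -> list[MatchResult]:
    """Score every database case; ascending by score, ties broken by case id."""
    if len(db) == 0:
        raise ValueError("database is empty")
    results = []
    for case_id in db.cases:
        score, t = match_score(patient, db.cases[case_id], max_iter=max_iter, tol_mm=tol_mm)
        results.append(MatchResult(
            case_id=case_id,
            translation_mm=t,
            score=score,
            n_points=len(patient),
            plan_path=db.plan_paths.get(case_id),
        ))
    results.sort(key=lambda r: (r.score, r.case_id))
    return results
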