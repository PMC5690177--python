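"""Automatic brain / eye / lens segmentation from head CT.

The chain needs no user interaction and no atlas: it thresholds the CT to the
soft-tissue window, then applies morphological reasoning to pick out organs by
shape.  The brain is the largest soft-tissue blob once thin muscle connections
are severed by erosion; the eyes are the two roundest remaining blobs, refined
by a Laplacian level set against the CT; each lens is the largest patch of
distinctly higher HU inside an eye's volume of interest, isolated with an
H-convex (regional-brightness) transform.

All structuring elements are Euclidean balls specified in millimetres, so the
operators behave identically across voxel spacings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import reconstruction

from ._morphology import (
    boundary_voxels,
    close_mm,
    connected_components,
    dilate_mm,
    erode_mm,
    largest_component,
)
from .core import BinaryMask, CTVolume
from .dicom_io import StructureSet

__all__ = [
    "SegmentationParams",
    "SegmentationResult",
    "DegenerateInputError",
    "soft_tissue_mask",
    "bone_edges",
    "segment_brain",
    "segment_eyes",
    "segment_lenses",
    "roundness",
    "segment_all",
]


class DegenerateInputError(ValueError):
    """The CT does not contain the anatomy the operator expects."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the segmentation chain (lengths in mm, HU where noted)."""

    soft_tissue_window: tuple[float, float] = (-200.0, 200.0)
    erosion_radius_mm: float = 2.0  # severs extraocular-muscle-scale bridges
    closing_radius_mm: float = 3.0
    hconvex_height: float = 40.0  # lens ~80-120 HU vs vitreous ~0-30 HU
    levelset_iterations: int = 50
    levelset_curvature_weight: float = 1.0
    levelset_feature_smoothing_mm: float = 1.0
    roundness_min: float = 0.8
    eye_voi_margin_mm: float = 3.0
    bone_edge_threshold: float = 100.0  # HU/mm gradient magnitude
    bone_barrier_dilation_mm: float = 1.0
    eye_erosion_mm: float = 1.5
    eye_closing_mm: float = 2.0
    lens_closing_mm: float = 1.0
    min_eye_candidate_mm3: float = 500.0
    roundness_method: str = "marching_cubes"

    def __post_init__(self) -> None:
        lo, hi = self.soft_tissue_window
        if lo >= hi:
            raise ValueError("soft-tissue window must be an increasing interval")
        for name in ("erosion_radius_mm", "closing_radius_mm", "eye_voi_margin_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SegmentationResult:
    brain: BinaryMask
    eye_L: BinaryMask
    eye_R: BinaryMask
    lens_L: BinaryMask
    lens_R: BinaryMask
    diagnostics: dict = field(default_factory=dict)

    def as_structure_set(self) -> StructureSet:
        return StructureSet({
            "brain": self.brain,
            "eye_L": self.eye_L,
            "eye_R": self.eye_R,
            "lens_L": self.lens_L,
            "lens_R": self.lens_R,
        })

    def structures(self) -> dict[str, BinaryMask]:
        return self.as_structure_set().masks


def soft_tissue_mask(ct: CTVolume,
                     window: tuple[float, float] = (-200.0, 200.0)) -> BinaryMask:
    """Voxels whose HU lies inside the soft-tissue window (inclusive)."""
    lo, hi = window
    grid = (ct.voxels >= lo) & (ct.voxels <= hi)
    if not grid.any():
        raise DegenerateInputError("no soft tissue in the CT volume")
    return BinaryMask(grid, ct.geometry)


def bone_edges(ct: CTVolume) -> np.ndarray:
    """3D Sobel gradient magnitude in HU/mm; maxima sit at soft-tissue/bone interfaces."""
    spacing = ct.geometry.spacing
    grad2 = np.zeros(ct.shape, dtype=np.float64)
    for axis in range(3):
        # Sobel = central difference (span 2*spacing) x smoothing (sum 16)
        g = ndimage.sobel(ct.voxels.astype(np.float64), axis=axis) / (32.0 * spacing[axis])
        grad2 += g * g
    return np.sqrt(grad2)


def segment_brain(ct: CTVolume, params: SegmentationParams = SegmentationParams()) -> BinaryMask:
    """Brain = largest soft-tissue component after bone-edge masking and erosion.

    Chain: soft-tissue mask -> subtract dilated bone edges -> binary closing ->
    erosion (severing thin connections) -> largest connected component ->
    dilation undoing the erosion -> binary closing.
    """
    spacing = ct.geometry.spacing
    soft = soft_tissue_mask(ct, params.soft_tissue_window).voxels

    edges = bone_edges(ct)
    barrier = edges > params.bone_edge_threshold
    if params.bone_barrier_dilation_mm > 0:
        barrier = dilate_mm(barrier, params.bone_barrier_dilation_mm, spacing)
    work = soft & ~barrier
    work = close_mm(work, params.closing_radius_mm, spacing) & soft

    eroded = erode_mm(work, params.erosion_radius_mm, spacing)
    if not eroded.any():
        raise DegenerateInputError("soft tissue vanished under erosion")
    core = largest_component(eroded)
    # undo the erosion and the thin boundary layer the edge barrier peeled off;
    # clipping to the soft-tissue mask keeps the recovery exact at bone
    recover = params.erosion_radius_mm + params.bone_barrier_dilation_mm \
        + float(spacing.max())
    brain = dilate_mm(core, recover, spacing) & soft
    brain = close_mm(brain, params.closing_radius_mm, spacing)
    brain = largest_component(brain)
    return BinaryMask(brain, ct.geometry)


def roundness(component: BinaryMask, method: str | None = None) -> float:
    """Sphericity: pi^(1/3) * (6V)^(2/3) / A, 1.0 for a perfect sphere.

    ``method`` selects the surface-area estimate: ``"marching_cubes"``
    (default; accurate for smooth shapes) or ``"voxel"`` (exposed-face
    counting; exact closed forms for boxes, but overestimates curved areas).
    """
    if component.is_empty():
        raise ValueError("roundness of an empty component is undefined")
    method = method or "marching_cubes"
    spacing = component.spacing
    volume = component.volume_mm3()
    if method == "marching_cubes":
        padded = np.pad(component.voxels, 1).astype(np.float64)
        verts, faces, _, _ = measure.marching_cubes(padded, 0.5, spacing=tuple(spacing))
        area = measure.mesh_surface_area(verts, faces)
    elif method == "voxel":
        area = 0.0
        face_areas = (
            spacing[1] * spacing[2],
            spacing[0] * spacing[2],
            spacing[0] * spacing[1],
        )
        m = component.voxels
        for axis, fa in enumerate(face_areas):
            padded = np.pad(m, [(1, 1) if a == axis else (0, 0) for a in range(3)])
            area += np.abs(np.diff(padded.astype(np.int8), axis=axis)).sum() * fa
    else:
        raise ValueError(f"unknown surface-area method {method!r}")
    score = float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area)
    return min(score, 1.0)


def _rank_eye_candidates(soft: np.ndarray, brain: np.ndarray,
                         ct: CTVolume, params: SegmentationParams):
    """All non-brain soft-tissue components with their roundness, sorted roundest first."""
    spacing = ct.geometry.spacing
    candidates = soft & ~dilate_mm(brain, 1.0, spacing)
    labels, n = connected_components(candidates)
    voxvol = ct.geometry.voxel_volume_mm3
    ranked = []
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    for lab in range(1, n + 1):
        if counts[lab] * voxvol < params.min_eye_candidate_mm3:
            continue
        comp = BinaryMask(labels == lab, ct.geometry)
        ranked.append((roundness(comp, params.roundness_method), lab, comp))
    ranked.sort(key=lambda t: (-t[0], t[1]))
    return ranked


def _levelset_refine(init: np.ndarray, hu_voi: np.ndarray, spacing: np.ndarray,
                     params: SegmentationParams) -> np.ndarray:
    """Laplacian level-set refinement of an initial mask against the CT."""
    import SimpleITK as sitk

    feature = sitk.GetImageFromArray(hu_voi.astype(np.float32).transpose(2, 1, 0))
    feature.SetSpacing(tuple(float(s) for s in spacing))
    if params.levelset_feature_smoothing_mm > 0:
        # the Laplacian speed term needs a noise-free second derivative
        feature = sitk.SmoothingRecursiveGaussian(
            feature, params.levelset_feature_smoothing_mm)
    seed = sitk.GetImageFromArray(init.astype(np.uint8).transpose(2, 1, 0))
    seed.SetSpacing(feature.GetSpacing())
    dist = sitk.SignedMaurerDistanceMap(
        seed, insideIsPositive=False, squaredDistance=False, useImageSpacing=True)
    ls = sitk.LaplacianSegmentationLevelSetImageFilter()
    ls.SetNumberOfIterations(int(params.levelset_iterations))
    ls.SetCurvatureScaling(float(params.levelset_curvature_weight))
    ls.SetPropagationScaling(1.0)
    # expand the eroded seed outward toward the globe boundary
    ls.SetReverseExpansionDirection(True)
    ls.SetMaximumRMSError(1e-6)  # run the full iteration budget deterministically
    out = ls.Execute(dist, feature)
    refined = sitk.GetArrayFromImage(out).transpose(2, 1, 0) <= 0.0
    return refined


def segment_eyes(ct: CTVolume, brain_mask: BinaryMask,
                 params: SegmentationParams = SegmentationParams()
                 ) -> tuple[BinaryMask, BinaryMask]:
    """Eyes = the two roundest non-brain soft-tissue components, refined.

    Per eye: lens-bright voxels are erased to the eye's median HU, the
    candidate is eroded to drop residual connections, a Laplacian level set
    re-adapts it to the CT, and a binary closing smooths the result.  Left and
    right are assigned by the sign of the x (left-right) centroid.
    """
    spacing = ct.geometry.spacing
    soft = soft_tissue_mask(ct, params.soft_tissue_window).voxels
    ranked = _rank_eye_candidates(soft, brain_mask.voxels, ct, params)
    eligible = [r for r in ranked if r[0] >= params.roundness_min]
    if len(eligible) < 2:
        raise DegenerateInputError(
            f"found {len(eligible)} eye candidates with roundness >= "
            f"{params.roundness_min}; need 2")

    refined = []
    for score, _, comp in eligible[:2]:
        idx = np.argwhere(comp.voxels)
        margin = np.ceil(params.eye_voi_margin_mm / spacing).astype(int) + 1
        lo = np.maximum(idx.min(axis=0) - margin, 0)
        hi = np.minimum(idx.max(axis=0) + margin + 1, comp.shape)
        voi = tuple(slice(a, b) for a, b in zip(lo, hi))

        sub = comp.voxels[voi]
        hu = np.array(ct.voxels[voi], dtype=np.float32)
        inside = hu[sub]
        background = float(np.median(inside))
        # erase the lens so the level set tracks the globe, not the bright patch
        bright = sub & (hu >= background + params.hconvex_height)
        hu[bright] = background

        eroded = erode_mm(sub, params.eye_erosion_mm, spacing)
        if not eroded.any():
            eroded = sub
        mask = _levelset_refine(eroded, hu, spacing, params)
        mask &= ~brain_mask.voxels[voi]
        if not mask.any() or _dice_arrays(mask, sub) < 0.5:
            # level set diverged from the candidate; fall back to the
            # morphological estimate (eroded candidate re-dilated)
            mask = dilate_mm(eroded, params.eye_erosion_mm, spacing) & sub
        mask = close_mm(mask, params.eye_closing_mm, spacing)
        mask = largest_component(mask)
        full = np.zeros(comp.shape, dtype=bool)
        full[voi] = mask
        refined.append(BinaryMask(full, ct.geometry))

    # larger x centroid = patient left
    xs = [m.centroid_mm()[0] for m in refined]
    left, right = (refined[0], refined[1]) if xs[0] >= xs[1] else (refined[1], refined[0])
    return left, right


def _dice_arrays(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    total = a.sum() + b.sum()
    return 2.0 * inter / total if total else 1.0


def h_convex(image: np.ndarray, height: float) -> np.ndarray:
    """H-convex transform: how far each voxel rises above its surroundings,
    capped at ``height`` (f minus the h-maxima reconstruction of f)."""
    seed = image - height
    rec = reconstruction(seed, image, method="dilation")
    return image - rec


def segment_lenses(ct: CTVolume, eyes: tuple[BinaryMask, BinaryMask],
                   params: SegmentationParams = SegmentationParams()
                   ) -> tuple[BinaryMask, BinaryMask]:
    """Lens = largest H-convex bright patch inside each eye's VOI, closed.

    An eye with no supra-threshold patch yields an empty mask with a warning.
    """
    spacing = ct.geometry.spacing
    out = []
    for label, eye in zip(("lens_L", "lens_R"), eyes):
        if eye.is_empty():
            raise ValueError("eye mask is empty")
        idx = np.argwhere(eye.voxels)
        margin = np.ceil(params.eye_voi_margin_mm / spacing).astype(int)
        lo = np.maximum(idx.min(axis=0) - margin, 0)
        hi = np.minimum(idx.max(axis=0) + margin + 1, eye.shape)
        voi = tuple(slice(a, b) for a, b in zip(lo, hi))

        hu = ct.voxels[voi].astype(np.float64)
        hconv = h_convex(hu, params.hconvex_height)
        # the lens must rise above the globe it sits in: restrict the bright
        # patches to the eye so plateaus elsewhere in the VOI cannot compete
        bright = (hconv > 1e-3) & dilate_mm(eye.voxels[voi], params.lens_closing_mm, spacing)
        full = np.zeros(eye.shape, dtype=bool)
        patch = largest_component(bright) if bright.any() else None
        # a patch spanning most of the globe is the globe's own brightness
        # plateau over the surrounding orbit, not a lens
        if patch is not None and patch.sum() <= 0.5 * eye.voxels[voi].sum():
            patch = close_mm(patch, params.lens_closing_mm, spacing)
            full[voi] = patch
        else:
            warnings.warn(f"no lens-bright patch found for {label}", stacklevel=2)
        out.append(BinaryMask(full, ct.geometry))
    return out[0], out[1]


def segment_all(ct: CTVolume,
                params: SegmentationParams = SegmentationParams()) -> SegmentationResult:
    """Run the full chain: brain, then eyes, then lenses. Deterministic."""
    brain = segment_brain(ct, params)
    eye_l, eye_r = segment_eyes(ct, brain, params)
    lens_l, lens_r = segment_lenses(ct, (eye_l, eye_r), params)
    diagnostics = {
        "volumes_mm3": {
            "brain": brain.volume_mm3(),
            "eye_L": eye_l.volume_mm3(),
            "eye_R": eye_r.volume_mm3(),
            "lens_L": lens_l.volume_mm3(),
            "lens_R": lens_r.volume_mm3(),
        },
    }
    return SegmentationResult(brain, eye_l, eye_r, lens_l, lens_r, diagnostics)
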