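"""Synthetic CT head phantoms with ground-truth masks and template plans.

The phantom is deliberately simple geometry — nested ellipsoids for scalp,
skull and brain, spheres for the eye globes, small ellipsoids for the lenses —
but it reproduces the anatomical facts the segmentation chain exploits: the
brain is the largest soft-tissue blob enclosed by bone, the eyes are the
roundest soft-tissue shapes, and each lens is a patch of distinctly higher
Hounsfield units inside its eye.  Optional thin "muscle" bridges connect the
eye region to the brain so the erosion step that severs extraocular-muscle
connections can be exercised.

A seeded jitter model perturbs the geometry to populate databases of prior
cases with realistic inter-patient variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import BinaryMask, CTVolume, ImageGeometry

__all__ = [
    "PhantomSpec",
    "JitterSpec",
    "PhantomGeometryError",
    "generate_phantom",
    "generate_database",
]

DEFAULT_HU = {
    "air": -1000.0,
    "scalp": 40.0,
    "skull": 700.0,
    "brain": 35.0,
    "eye": 25.0,
    "lens": 110.0,
    "muscle": 45.0,
}

SOFT_TISSUE_WINDOW = (-200.0, 200.0)


class PhantomGeometryError(ValueError):
    """Raised when a spec describes anatomy that cannot be rasterized legally."""


@dataclass(frozen=True)
class JitterSpec:
    """Uniform (+/- magnitude, mm) perturbations applied per database case.

    Magnitudes emulate the inter-patient spread of head size, brain shape and
    orbit position seen across adult whole-brain patients.
    """

    head_semiaxes_mm: float = 2.0
    brain_semiaxes_mm: float = 3.0
    brain_center_mm: float = 2.0
    eye_center_mm: float = 2.0
    eye_radius_mm: float = 1.0

    def as_dict(self) -> dict[str, float]:
        return {
            "head_semiaxes_mm": self.head_semiaxes_mm,
            "brain_semiaxes_mm": self.brain_semiaxes_mm,
            "brain_center_mm": self.brain_center_mm,
            "eye_center_mm": self.eye_center_mm,
            "eye_radius_mm": self.eye_radius_mm,
        }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity description of one synthetic head.

    All lengths in mm, patient axes x=left-right, y=anterior(-)/posterior(+),
    z=inferior(-)/superior(+); offsets are relative to the head centre.
    """

    grid_shape: tuple[int, int, int] = (160, 196, 172)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    head_semiaxes_mm: tuple[float, float, float] = (72.0, 90.0, 78.0)
    scalp_thickness_mm: float = 5.0
    skull_thickness_mm: float = 6.0
    brain_semiaxes_mm: tuple[float, float, float] = (52.0, 62.0, 55.0)
    brain_center_offset_mm: tuple[float, float, float] = (0.0, 12.0, 10.0)
    eye_radius_mm: float = 10.0
    # left eye sits at +x (patient left), both anterior (-y) and inferior (-z)
    eye_center_offsets_mm: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "eye_L": (24.0, -62.0, -22.0),
            "eye_R": (-24.0, -62.0, -22.0),
        }
    )
    lens_semiaxes_mm: tuple[float, float, float] = (4.0, 2.5, 4.0)
    lens_anterior_offset_mm: float = 7.0
    # air gap isolating each globe; wide enough to survive 26-connectivity
    # labelling at coarse (2-3 mm) voxel spacings
    socket_margin_mm: float = 4.0
    bridge_radius_mm: float = 0.0  # >0 adds eye-brain muscle bridges
    hu_values: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HU))
    noise_hu_sigma: float = 5.0
    rng_seed: int = 0
    jitter: JitterSpec = field(default_factory=JitterSpec)

    def validate(self) -> None:
        hu = self.hu_values
        lo, hi = SOFT_TISSUE_WINDOW
        for role in ("brain", "eye", "scalp"):
            if not lo <= hu[role] <= hi:
                raise PhantomGeometryError(f"hu_values[{role!r}] must lie in {SOFT_TISSUE_WINDOW}")
        if hu["skull"] <= hi:
            raise PhantomGeometryError("skull HU must exceed the soft-tissue window")
        if hu["air"] >= lo:
            raise PhantomGeometryError("air HU must fall below the soft-tissue window")
        if hu["lens"] <= hu["eye"]:
            raise PhantomGeometryError("lens HU must exceed eye HU")
        if self.skull_thickness_mm <= 0 or self.eye_radius_mm <= 0:
            raise PhantomGeometryError("thicknesses and radii must be positive")
        if set(self.eye_center_offsets_mm) != {"eye_L", "eye_R"}:
            raise PhantomGeometryError("eye offsets must be given for eye_L and eye_R")
        if self.eye_center_offsets_mm["eye_L"][0] <= self.eye_center_offsets_mm["eye_R"][0]:
            raise PhantomGeometryError("eye_L must sit at larger x (patient left) than eye_R")


def _ellipsoid(coords: tuple[np.ndarray, np.ndarray, np.ndarray],
               center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - center[0]) / semiaxes[0]) ** 2
        + ((y - center[1]) / semiaxes[1]) ** 2
        + ((z - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _cylinder(coords, p0: np.ndarray, p1: np.ndarray, radius: float) -> np.ndarray:
    """Finite cylinder of given radius between p0 and p1."""
    x, y, z = coords
    d = p1 - p0
    length2 = float(d @ d)
    px, py, pz = x - p0[0], y - p0[1], z - p0[2]
    t = (px * d[0] + py * d[1] + pz * d[2]) / length2
    t = np.clip(t, 0.0, 1.0)
    dist2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
    return dist2 <= radius**2


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, dict[str, BinaryMask]]:
    """Rasterize one phantom.

    Returns the CT volume (with seeded Gaussian noise if requested) and the
    ground-truth masks: brain, eye_L, eye_R, lens_L, lens_R, external, plus
    skull and soft_tissue masks used by validation tests.  Deterministic for a
    fixed spec (including ``rng_seed``).
    """
    spec.validate()
    shape = tuple(int(n) for n in spec.grid_shape)
    geom = ImageGeometry(spacing_mm=tuple(float(s) for s in spec.spacing_mm))
    spacing = geom.spacing

    center = (np.asarray(shape) - 1.0) * spacing / 2.0
    head_ax = np.asarray(spec.head_semiaxes_mm, dtype=float)
    brain_ax = np.asarray(spec.brain_semiaxes_mm, dtype=float)
    brain_c = center + np.asarray(spec.brain_center_offset_mm, dtype=float)
    skull_ax = brain_ax + spec.skull_thickness_mm
    scalp_ax = skull_ax + spec.scalp_thickness_mm

    # physical voxel-center coordinates along each axis
    grids = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    coords = tuple(g * s for g, s in zip(grids, spacing))

    # head_semiaxes_mm sizes the grid; the rendered head is a thin scalp shell
    # over the skull plus a capsule around each orbit, which keeps the brain
    # the largest soft-tissue blob as in real heads.
    extent = (np.asarray(shape) - 1.0) * spacing
    if np.any(center - head_ax < 0) or np.any(center + head_ax > extent):
        raise PhantomGeometryError("head ellipsoid exceeds the grid")

    brain = _ellipsoid(coords, brain_c, brain_ax)
    skull_outer = _ellipsoid(coords, brain_c, skull_ax)
    scalp_outer = _ellipsoid(coords, brain_c, scalp_ax)

    eyes: dict[str, np.ndarray] = {}
    sockets: dict[str, np.ndarray] = {}
    capsules: dict[str, np.ndarray] = {}
    lenses: dict[str, np.ndarray] = {}
    eye_r = float(spec.eye_radius_mm)
    capsule_r = eye_r + spec.socket_margin_mm + spec.scalp_thickness_mm
    for side in ("eye_L", "eye_R"):
        ec = center + np.asarray(spec.eye_center_offsets_mm[side], dtype=float)
        sphere_ax = np.full(3, eye_r)
        eye = _ellipsoid(coords, ec, sphere_ax)
        socket = _ellipsoid(coords, ec, sphere_ax + spec.socket_margin_mm)
        capsule = _ellipsoid(coords, ec, np.full(3, capsule_r))
        lens_c = ec + np.array([0.0, -spec.lens_anterior_offset_mm, 0.0])
        lens = _ellipsoid(coords, lens_c, np.asarray(spec.lens_semiaxes_mm, dtype=float))
        if np.any(eye & brain):
            raise PhantomGeometryError(f"{side} overlaps the brain")
        if np.any(lens & ~eye):
            raise PhantomGeometryError(f"lens of {side} is not contained in the eye")
        eyes[side], sockets[side], capsules[side], lenses[side] = eye, socket, capsule, lens
    if np.any(eyes["eye_L"] & eyes["eye_R"]):
        raise PhantomGeometryError("eyes overlap each other")

    hu = spec.hu_values
    head = scalp_outer | capsules["eye_L"] | capsules["eye_R"]
    # orbital soft tissue bridging each capsule to the cranium, so the head is
    # one body however the jitter displaces the orbits
    for side in ("eye_L", "eye_R"):
        ec = center + np.asarray(spec.eye_center_offsets_mm[side], dtype=float)
        head |= _cylinder(coords, ec, brain_c, capsule_r)
    if head[0, :, :].any() or head[-1, :, :].any() or head[:, 0, :].any() \
            or head[:, -1, :].any() or head[:, :, 0].any() or head[:, :, -1].any():
        raise PhantomGeometryError("head exceeds the grid")
    from ._morphology import connected_components

    _, n_head = connected_components(head)
    if n_head != 1:
        raise PhantomGeometryError("head is not a single connected body")
    vol = np.full(shape, hu["air"], dtype=np.float32)
    vol[head] = hu["scalp"]
    vol[skull_outer & ~brain] = hu["skull"]
    vol[brain] = hu["brain"]
    for side in ("eye_L", "eye_R"):
        vol[sockets[side] & ~brain] = hu["air"]
    if spec.bridge_radius_mm > 0:
        for side in ("eye_L", "eye_R"):
            ec = center + np.asarray(spec.eye_center_offsets_mm[side], dtype=float)
            bridge = _cylinder(coords, ec, brain_c, spec.bridge_radius_mm)
            vol[bridge & ~brain] = hu["muscle"]
    for side in ("eye_L", "eye_R"):
        vol[eyes[side]] = hu["eye"]
        vol[lenses[side]] = hu["lens"]

    lo, hi = SOFT_TISSUE_WINDOW
    soft_truth = (vol >= lo) & (vol <= hi)

    # contract: the brain must be the largest connected soft-tissue structure
    labels, n = connected_components(soft_truth)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    counts[0] = 0
    brain_label = labels[tuple(np.round(brain_c / spacing).astype(int))]
    if brain_label == 0 or counts.argmax() != brain_label:
        raise PhantomGeometryError("brain is not the largest soft-tissue component")

    if spec.noise_hu_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        vol = vol + rng.normal(0.0, spec.noise_hu_sigma, size=shape).astype(np.float32)

    masks = {
        "brain": BinaryMask(brain, geom),
        "eye_L": BinaryMask(eyes["eye_L"], geom),
        "eye_R": BinaryMask(eyes["eye_R"], geom),
        "lens_L": BinaryMask(lenses["eye_L"], geom),
        "lens_R": BinaryMask(lenses["eye_R"], geom),
        "external": BinaryMask(head, geom),
        "skull": BinaryMask(skull_outer & ~brain, geom),
        "soft_tissue": BinaryMask(soft_truth, geom),
    }
    return CTVolume(vol, geom), masks


def _jittered_spec(spec: PhantomSpec, rng: np.random.Generator, seed: int) -> PhantomSpec:
    j = spec.jitter
    u = lambda m, n=3: rng.uniform(-m, m, size=n)
    offsets = {
        side: tuple(np.asarray(off) + u(j.eye_center_mm))
        for side, off in spec.eye_center_offsets_mm.items()
    }
    eye_r = float(spec.eye_radius_mm + rng.uniform(-j.eye_radius_mm, j.eye_radius_mm))
    # lens geometry scales with the globe so it stays inside the jittered eye
    scale = eye_r / spec.eye_radius_mm
    return replace(
        spec,
        head_semiaxes_mm=tuple(np.asarray(spec.head_semiaxes_mm) + u(j.head_semiaxes_mm)),
        brain_semiaxes_mm=tuple(np.asarray(spec.brain_semiaxes_mm) + u(j.brain_semiaxes_mm)),
        brain_center_offset_mm=tuple(
            np.asarray(spec.brain_center_offset_mm) + u(j.brain_center_mm)
        ),
        eye_center_offsets_mm=offsets,
        eye_radius_mm=eye_r,
        lens_semiaxes_mm=tuple(np.asarray(spec.lens_semiaxes_mm) * scale),
        lens_anterior_offset_mm=float(spec.lens_anterior_offset_mm * scale),
        rng_seed=seed,
    )


def generate_database(
    spec: PhantomSpec, n_cases: int
) -> list[tuple[CTVolume, dict[str, BinaryMask], "object"]]:
    """Generate ``n_cases`` jittered phantoms, each with a two-beam template plan.

    Every case receives a synthetic plan with two lateral opposed beams
    (gantry 90/270 degrees), isocenter at the case's brain centroid,
    placeholder rectangular MLC apertures and unique patient metadata.
    """
    from .dicom_io import make_template_plan

    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    master = np.random.default_rng(spec.rng_seed)
    cases = []
    for i in range(n_cases):
        case_seed = int(master.integers(0, 2**31 - 1))
        jspec = _jittered_spec(spec, master, case_seed)
        ct, masks = generate_phantom(jspec)
        iso = masks["brain"].centroid_mm()
        plan = make_template_plan(
            patient_name=f"Phantom^Case{i:03d}",
            patient_id=f"PH{i:04d}",
            isocenter_mm=tuple(float(v) for v in iso),
        )
        cases.append((ct, masks, plan))
    return cases
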