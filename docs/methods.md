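# Methods

This note records the models, algorithms and design choices behind the
package, in enough detail to reproduce or re-derive its behaviour.

## Problem setting

Whole-brain radiotherapy (WBRT) delivers a uniform dose to the brain through
two opposed lateral photon beams, with the multileaf collimator (MLC) shaped
at the brain–eye interface to spare the eyes and lenses. Planning such a
treatment is technically simple but repetitive: contour the brain and ocular
structures, place the lateral beams, and iterate the MLC aperture. The
package automates the whole chain as a retrieval problem: segment the new
patient's CT, find the prior case with the most similar anatomy in a database
of validated plans, and reuse that case's plan after updating patient
identity and isocenter. Dose calculation is deliberately out of scope — the
retargeted plan is meant to be imported into a treatment planning system,
where the prescription is entered and dose recomputed.

## Coordinate conventions

All geometry lives in DICOM LPS patient coordinates: x toward the patient's
left (the lateral beam axis), y toward posterior, z toward superior. Voxel
grids are indexed (x, y, z) in that same frame. Non-axis-aligned CT series
are resampled to axis-aligned at read time (linear interpolation for HU),
because the similarity score needs well-defined y and z axes.

## Segmentation

The chain is purely morphological; its only input is the CT volume.

1. **Soft-tissue mask** — voxels with HU in [−200, 200] (inclusive). Air and
   bone fall outside this window for any calibrated CT.
2. **Bone-edge barrier** — 3D Sobel gradient magnitude, normalised to HU/mm
   (the Sobel kernel's central difference spans two voxels and its smoothing
   weights sum to 16 per transverse axis, hence the 1/(32·spacing) factor).
   Voxels above 100 HU/mm, dilated by 1 mm, are removed from the soft-tissue
   mask so that soft tissue on opposite sides of thin bone cannot merge.
3. **Brain** — binary closing (3 mm), erosion by a 2 mm Euclidean ball to
   sever muscle-scale connections (the extraocular muscles are the clinically
   relevant culprit), largest 26-connected component, then a recovery
   dilation and closing. The recovery radius is the erosion radius plus the
   barrier width (barrier dilation + one voxel), and the result is clipped to
   the soft-tissue mask, so the erosion and edge peel are undone exactly at
   bone interfaces without re-merging severed bridges.
4. **Eyes** — among soft-tissue components disjoint from the (slightly
   dilated) brain and larger than 500 mm³, the two roundest with
   sphericity ≥ 0.8 are taken as eye candidates; fewer than two is an error.
   Each candidate is refined: lens-bright voxels (≥ median + 40 HU) are
   erased to the candidate's median HU so the level set tracks the globe;
   the candidate is eroded 1.5 mm; a Laplacian level set (50 iterations,
   curvature weight 1.0, propagation 1.0, expansion direction outward)
   re-adapts it to the CT; binary closing (2 mm) smooths the result. The
   level-set feature image is Gaussian-smoothed (σ = 1 mm) first — the
   Laplacian speed term is a second derivative and is unusable on raw noisy
   HU. If the level set diverges (Dice < 0.5 against its own candidate) the
   morphological estimate is kept instead. Left/right assignment is by the
   sign of the x centroid.
5. **Lenses** — inside each eye's bounding box grown by 3 mm, the H-convex
   transform (f minus the h-maxima reconstruction of f, h = 40 HU) isolates
   regions at least 40 HU brighter than their surroundings. Supra-threshold
   voxels are restricted to the globe, the largest component is kept and
   closed (1 mm). Two degenerate outcomes are handled explicitly: no bright
   patch, and a "patch" covering more than half the globe — the latter is
   the globe's own brightness plateau over the dark orbit (exactly what the
   H-convex transform reports for a lens-free uniform globe) and both yield
   an empty lens mask plus a warning rather than an error.

**Roundness** is sphericity, π^(1/3)·(6V)^(2/3)/A, clamped to [0, 1]. The
surface area A defaults to a marching-cubes mesh estimate, which is accurate
for smooth shapes (a rasterised sphere scores ≈ 0.98). A face-counting
estimator is available (`method="voxel"`); it is exact for boxes (a single
voxel scores π^(1/3)·6^(2/3)/6 ≈ 0.806) but overestimates curved surface
area by up to 50 %, which would push spheres to ≈ 0.67 — hence it is not the
default for ranking.

All structuring elements are Euclidean balls specified in millimetres and
realised through exact Euclidean distance transforms, so the operators are
invariant to voxel spacing and anisotropy. Connected components use
26-connectivity throughout. The chain is fully deterministic.

## Agreement metrics

Dice = 2|A∩B|/(|A|+|B|); undefined (error) when both masks are empty.
Surface distances are computed between boundary-voxel centres (face-connected
boundary) in mm: the mean pools the directed distances from both surfaces;
the Hausdorff distance is the maximum over both directions. Both are
symmetric, and Hausdorff ≥ mean ≥ 0 always. No sub-voxel interpolation is
attempted; the implementation is verified against a brute-force O(n²)
pairwise-distance oracle to 1e-9 mm.

## Case retrieval

Matching uses structure sets only — the database index stores decimated
surface point clouds and plan file paths, never CT data.

- **Surfaces** — boundary-voxel centres in mm, uniformly decimated to at
  most 2000 points per structure with a fixed-seed sampler (reproducible).
- **Cropping** — the posterior/superior brain surface is irradiated by the
  open field and irrelevant to MLC fit, so brain points behind a plane are
  discarded. The default plane passes through the superior pole of the eye
  globes with its normal tilted 15° from +z toward −y (nape-to-forehead);
  both the anchor and tilt are configurable, as no canonical values exist.
  The side of the plane containing the eye centroids is kept; eye surfaces
  are never cropped.
- **ICP** — translations only (patients differ by couch set-up, not
  rotation, and a richer transform would hide real anatomical differences).
  Initialised at the centroid difference; each iteration re-assigns nearest
  neighbours and moves by the mean residual; stops at an update below
  1e-3 mm or 100 iterations.
- **Score** — after alignment,

      score = sqrt( (1/N) Σᵢ [ (Δyᵢ)² + (Δzᵢ)² ] )

  where Δ is the residual of patient point i to its full-3D nearest
  database point, and only the y/z components enter. The x component is
  discarded: with lateral opposed beams, left-right offsets barely move the
  dose, while y/z mismatches cross the MLC-shaped field edge. The square
  penalises a large localized mismatch over a small uniform one — a 7 mm
  patch on 10 % of the surface (rest 1 mm) scores √(0.1·49 + 0.9·1) ≈ 2.41,
  worse than a uniform 2 mm offset (2.00), whereas a plain mean distance
  would rank them the other way (1.6 vs 2.0). The 1/N normalisation makes
  scores comparable across clouds of different sizes. The sum is
  one-directional, over the patient's points; brain and eye points are
  pooled with equal weight (a per-structure weight would be easy to add but
  there is no evidence to set it to anything but 1).

Ranking scores every database case and sorts ascending, ties broken by case
id. Because the best score over a superset can only improve, nested
databases give non-increasing best scores by construction; the tests verify
this on 10/20/30/70-case nested synthetic databases.

## Plan retargeting

The best match's plan is copied; patient name and ID are replaced; fresh SOP/
series/study instance UIDs are generated; and the isocenter is mapped into
the new patient's frame by the **inverse** of the ICP translation (ICP
aligned patient → database, so database geometry returns by subtracting the
translation). Nothing else changes — beams, jaws, MLC sequences and monitor
units pass through byte-identical, which an attribute-level diff harness
verifies. Prescription dose is not stored in RT plan files and is left for
the planning system. The isocenter rule is a design decision of this
package; other conventions (e.g. re-centring on the new brain centroid)
could be substituted at the same code point.

## Synthetic phantom

The phantom emulates exactly the anatomical regularities the pipeline
exploits, with analytic ground truth:

- brain: ellipsoid, default semiaxes (52, 62, 55) mm — the largest
  soft-tissue body (HU 35);
- skull: 6 mm ellipsoidal shell around the brain (HU 700);
- scalp: 5 mm shell over the skull plus an orbital capsule and connector
  around each eye (HU 40) — kept thin so that, as in real heads, the scalp
  blob stays smaller than the brain;
- eyes: 10 mm spheres (HU 25) in air-gap sockets (4 mm) that isolate them
  from surrounding soft tissue on grids as coarse as 2–3 mm;
- lenses: small ellipsoids (4 × 2.5 × 4 mm) at the anterior pole of each
  globe, HU 110 — the high-HU patch the H-convex step hunts;
- optional 1 mm-radius "muscle" cylinders from globe to brain to exercise
  the erosion step;
- additive Gaussian noise, σ = 5 HU, seeded.

Voxel spacing defaults to 1 mm isotropic (grid 160×196×172). A jitter model
perturbs brain semiaxes (±3 mm), brain centre (±2 mm), eye centres (±2 mm)
and eye radius (±1 mm) per database case with independent uniform draws —
roughly the inter-patient spread of adult head anatomy — and every case gets
a two-beam lateral template plan (gantry 90°/270°, placeholder rectangular
MLC, isocenter at the case's brain centroid) with unique patient metadata.
The generator validates its own contracts (lens ⊂ eye ⊂ head, eyes disjoint
from brain, brain the largest soft-tissue component, head inside the grid)
and rejects illegal specifications.

What the phantom does **not** model: CT texture and streak artefacts, bone
heterogeneity, partial-volume effects at structure boundaries, anatomical
asymmetry, and pathology. Passing the recovery tests therefore shows the
operator chain implements its intended logic and is robust to moderate noise
and geometric variation — not that it reaches clinical accuracy on real
patients, where reported segmentation agreement is necessarily lower for
small structures like the lens.

## Problem sizes and numerical choices

- Segmentation-recovery studies run 20 jittered phantoms at 1 mm spacing
  (the spacing the Dice targets refer to); retrieval studies use 70-case
  databases generated at 2 mm spacing, since matching consumes surfaces in
  mm and never touches HU data.
- The acceptance script (`scripts/acceptance.py`) uses a 10-phantom
  segmentation cohort and the full 70-case retrieval study; all randomness
  derives from its `--seed`.
- Distance-transform morphology uses strict `> r` for erosion and `<= r`
  for dilation, making open/close exact inverses on solids with smooth
  boundaries at the operator scale.
- The H-convex threshold is 1e-3 HU above zero (exact zero is unstable in
  float); the lens plateau rejection triggers at 50 % of globe volume.
- Ties in ranking break lexicographically on case id; the largest-component
  rule breaks ties by label order (first-found).
- DICOM CT is written as int16 HU with identity rescale; round trips are
  exact for integer-valued volumes. RTSTRUCT contours are the 0.5-level
  curves of each mask slice; rasterisation uses voxel-centre-in-polygon
  ownership, giving round-trip Dice ≥ 0.99 on phantom structures.

## Known limitations

- The crop-plane position and tilt are conventions, not fitted values; the
  retrieval ordering can depend on them for near-tied cases.
- Translations-only ICP will not correct head tilt; a rotated set-up would
  inflate scores for all candidates alike.
- The segmentation assumes a skull-enclosed brain and two visible globes:
  post-surgical anatomy, prostheses or a cropped field of view violate its
  preconditions (the chain raises rather than guessing).
- The retrieval score is validated against constructed scenarios and
  synthetic cohorts; its clinical discrimination can only be established on
  real plan databases, which this package does not ship.
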