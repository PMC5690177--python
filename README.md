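# brainplan

Automated treatment planning for whole-brain radiotherapy (WBRT): segment
the brain, eyes and lenses from a head CT with no user interaction, retrieve
the most anatomically similar prior case from a database of validated plans,
and reuse that case's DICOM RT plan for the new patient.

WBRT uses two opposed lateral beams with the multileaf collimator (MLC)
shaped at the brain–eye interface. The plan quality therefore hinges on how
well the template's MLC aperture fits the new patient's brain–eye anatomy —
a matching problem, not an optimisation problem. `brainplan` is aimed at
medical-physics researchers studying knowledge-based (case-retrieval)
planning; it ships a synthetic head-phantom generator so every stage is
testable without clinical data.

## Method

1. **Segmentation** (morphological, CT-only): threshold to the soft-tissue
   window [−200, 200] HU; subtract dilated Sobel bone edges; erode with a
   2 mm ball to sever muscle-scale connections; the **brain** is the largest
   connected component (recovered by dilation + closing). The **eyes** are
   the two roundest remaining components (sphericity
   π^⅓(6V)^⅔/A ≥ 0.8), refined by a Laplacian level set against the CT.
   Each **lens** is the largest H-convex bright patch (h = 40 HU) inside its
   eye's volume of interest.
2. **Retrieval**: structure surfaces become point clouds (boundary-voxel
   centres, decimated to ≤ 2000 points); posterior/superior brain surface is
   cropped away by a nape-to-forehead plane; a translations-only ICP aligns
   patient to each database case; the similarity score is

   `score = sqrt( (1/N) Σ_i [ (y_i − closest(p_i)_y)² + (z_i − closest(p_i)_z)² ] )`

   — an RMS over the anterior–posterior (y) and superior–inferior (z)
   residual components to the full-3D nearest neighbour. Left–right (x)
   residuals are ignored (lateral beams make them dosimetrically inert) and
   squaring penalises localized discrepancies, which are what break MLC fit.
   Lower is better; the best match's plan is retrieved.
3. **Retargeting**: the template plan is copied with new patient
   name/ID, fresh UIDs, and the isocenter mapped back through the inverse
   ICP translation. Beams, jaws, MLC sequences and monitor units are
   preserved byte-for-byte. Prescription dose and dose computation are left
   to the treatment planning system.

See `docs/methods.md` for parameter defaults, numerical choices and the
phantom's anatomy model.

## Worked example

Everything below runs on synthetic data generated on the fly.

```sh
# a 1 mm synthetic head CT with ground-truth structures
brainplan phantom --out patient --seed 7 --spacing 1.0

# automatic segmentation, then compare against the ground truth
brainplan segment  --ct patient/ct.npz --out seg.npz
brainplan evaluate --test seg.npz --reference patient/ground_truth.npz
```

The evaluation prints per-structure agreement; on this phantom:

```json
{
  "brain":  {"dice": 0.9972, "mean_surface_distance_mm": 0.13, "hausdorff_mm": 1.0},
  "eye_L":  {"dice": 1.0, "mean_surface_distance_mm": 0.0, "hausdorff_mm": 0.0},
  "eye_R":  {"dice": 1.0, "mean_surface_distance_mm": 0.0, "hausdorff_mm": 0.0},
  "lens_L": {"dice": 1.0, "mean_surface_distance_mm": 0.0, "hausdorff_mm": 0.0},
  "lens_R": {"dice": 1.0, "mean_surface_distance_mm": 0.0, "hausdorff_mm": 0.0}
}
```

Dice 1.0 means the mask is voxel-identical to the ground-truth solid; the
brain's 0.997 reflects a sub-voxel boundary difference (mean surface
distance 0.13 mm). Real CTs will not reach these values — the phantom is
noise-perturbed but geometrically clean.

With a database of prior cases (here 10 jittered synthetic cases, each
holding `structures.npz` and `plan.dcm` in its own subdirectory):

```sh
brainplan build-db --cases cases/ --out db/
brainplan autoplan --ct patient/ct.npz --db db/ --out auto/ \
                   --patient-name "Demo^Patient" --patient-id DEMO01
# -> retargeted plan written to auto/plan.dcm (template case02, score 1.47 mm)
```

The score is the RMS y/z surface mismatch after alignment: 1.47 mm means the
best template's brain–eye region deviates from this patient by about a
millimetre and a half where the MLC has to fit. `auto/match.json` lists every
case ranked (here 1.47, 1.49, 1.63, … mm); `auto/plan.dcm` carries the
template's beams and MLC verbatim with the new identity and isocenter.

The same functionality is available as a library:

```python
from brainplan import PhantomSpec, generate_phantom, segment_all

ct, truth = generate_phantom(PhantomSpec(rng_seed=7))
result = segment_all(ct)          # SegmentationResult with 5 masks
print(result.diagnostics["volumes_mm3"])
```

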