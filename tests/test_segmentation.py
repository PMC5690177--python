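"""The morphological segmentation chain: operator correctness on constructed
volumes, and recovery of the phantom's ground-truth anatomy."""

import dataclasses
import warnings

import numpy as np
import pytest

from brainplan.core import BinaryMask, CTVolume, ImageGeometry
from brainplan.phantom import PhantomSpec, generate_phantom
from brainplan.segmentation import (
    DegenerateInputError,
    SegmentationParams,
    bone_edges,
    roundness,
    segment_brain,
    segment_eyes,
    segment_lenses,
    soft_tissue_mask,
)
from tests.conftest import dice_masks

GEOM1 = ImageGeometry(spacing_mm=(1.0, 1.0, 1.0))


def uniform_ct(shape, hu, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.full(shape, hu, dtype=np.float32),
                    ImageGeometry(spacing_mm=spacing))


class TestSoftTissueMask:
    def test_uniform_zero_volume_is_all_soft(self):
        mask = soft_tissue_mask(uniform_ct((8, 8, 8), 0.0))
        assert mask.voxels.all()

    def test_excludes_bone_and_air(self, default_phantom):
        ct, gt = default_phantom
        mask = soft_tissue_mask(ct)
        assert not np.any(mask.voxels & gt["skull"].voxels)
        assert np.any(mask.voxels)

    def test_matches_generated_solids(self, default_phantom):
        ct, gt = default_phantom
        mask = soft_tissue_mask(ct)
        truth = gt["soft_tissue"].voxels
        assert mask.voxels.sum() == pytest.approx(truth.sum(), rel=0.03)

    def test_all_air_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            soft_tissue_mask(uniform_ct((8, 8, 8), -1000.0))


class TestBoneEdges:
    def test_constant_volume_has_zero_edges(self):
        assert np.allclose(bone_edges(uniform_ct((10, 10, 10), 50.0)), 0.0)

    def test_step_response_proportional_to_height(self):
        def step_ct(h):
            v = np.zeros((12, 12, 12), dtype=np.float32)
            v[6:, :, :] = h
            return CTVolume(v, GEOM1)

        e1 = bone_edges(step_ct(100.0)).max()
        e2 = bone_edges(step_ct(300.0)).max()
        assert e2 == pytest.approx(3.0 * e1, rel=1e-6)

    def test_skull_interface_is_strong_and_brain_interior_quiet(self, default_phantom):
        from brainplan._morphology import boundary_voxels, erode_mm

        ct, gt = default_phantom
        edges = bone_edges(ct)
        shell = boundary_voxels(gt["skull"].voxels)
        # bone/soft contrast ~660 HU over 2 mm: interface gradients must
        # clear the default barrier threshold almost everywhere
        assert (edges[shell] > 100.0).mean() > 0.9
        interior = erode_mm(gt["brain"].voxels, 4.0, ct.geometry.spacing)
        assert np.median(edges[interior]) < 20.0


class TestSegmentBrain:
    def test_picks_largest_soft_blob(self):
        v = np.full((40, 20, 20), -1000.0, dtype=np.float32)
        v[2:12, 2:12, 2:12] = 50.0   # 1000 voxels
        v[25:30, 4:9, 4:10] = 50.0   # 150 voxels
        ct = CTVolume(v, GEOM1)
        params = SegmentationParams(erosion_radius_mm=1.0, closing_radius_mm=1.0)
        brain = segment_brain(ct, params)
        assert brain.voxels[5, 5, 5]
        assert not brain.voxels[27, 6, 6]

    def test_muscle_bridges_are_severed(self):
        ct, gt = generate_phantom(PhantomSpec(bridge_radius_mm=1.0))
        brain = segment_brain(ct)
        assert not np.any(brain.voxels & gt["eye_L"].voxels)
        assert not np.any(brain.voxels & gt["eye_R"].voxels)
        assert dice_masks(brain, gt["brain"]) >= 0.95

    def test_phantom_recovery(self, default_phantom, default_segmentation):
        _, gt = default_phantom
        assert dice_masks(default_segmentation.brain, gt["brain"]) >= 0.95

    def test_erosion_radius_insensitive_on_clean_anatomy(self, default_phantom):
        ct, gt = default_phantom
        d = {}
        for radius in (1.0, 3.0):
            params = SegmentationParams(erosion_radius_mm=radius)
            d[radius] = dice_masks(segment_brain(ct, params), gt["brain"])
        assert abs(d[1.0] - d[3.0]) <= 0.02


class TestRoundness:
    def test_single_voxel_cube_closed_form(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        expected = np.pi ** (1 / 3) * 6.0 ** (2 / 3) / 6.0  # ~0.806
        assert roundness(BinaryMask(m, GEOM1), method="voxel") == pytest.approx(expected, abs=1e-9)

    def test_rasterized_sphere_is_round(self):
        idx = np.indices((50, 50, 50))
        d2 = sum((idx[a] - 24.5) ** 2 for a in range(3))
        sphere = d2 <= (20.0) ** 2
        mask = BinaryMask(sphere, ImageGeometry(spacing_mm=(0.5, 0.5, 0.5)))
        assert roundness(mask) >= 0.9

    def test_thin_slab_is_not_round(self):
        slab = np.zeros((25, 25, 5), dtype=bool)
        slab[2:23, 2:23, 2] = True
        assert roundness(BinaryMask(slab, GEOM1)) < 0.5

    def test_sphere_beats_equal_volume_slab(self):
        idx = np.indices((30, 30, 30))
        d2 = sum((idx[a] - 14.5) ** 2 for a in range(3))
        sphere = BinaryMask(d2 <= 100.0, GEOM1)
        n = int(sphere.voxels.sum())
        side = int(np.ceil(np.sqrt(n)))
        slab_grid = np.zeros((side + 2, side + 2, 3), dtype=bool)
        filled = 0
        for i in range(side):
            take = min(side, n - filled)
            slab_grid[1 + i, 1:1 + take, 1] = True
            filled += take
            if filled >= n:
                break
        slab = BinaryMask(slab_grid, GEOM1)
        assert roundness(sphere) > roundness(slab)

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            roundness(BinaryMask(np.zeros((3, 3, 3), dtype=bool), GEOM1))


class TestSegmentEyes:
    def test_phantom_recovery(self, default_phantom, default_segmentation):
        _, gt = default_phantom
        assert dice_masks(default_segmentation.eye_L, gt["eye_L"]) >= 0.85
        assert dice_masks(default_segmentation.eye_R, gt["eye_R"]) >= 0.85

    def test_left_right_assignment(self, default_phantom, default_segmentation):
        _, gt = default_phantom
        assert default_segmentation.eye_L.centroid_mm()[0] > \
            default_segmentation.eye_R.centroid_mm()[0]

    def test_single_eye_is_an_error(self, default_phantom, default_segmentation):
        ct, gt = default_phantom
        maimed = CTVolume(ct.voxels.copy(), ct.geometry)
        maimed.voxels[gt["eye_R"].voxels] = -1000.0
        with pytest.raises(DegenerateInputError):
            segment_eyes(maimed, default_segmentation.brain)


class TestSegmentLenses:
    def test_phantom_recovery(self, default_phantom, default_segmentation):
        _, gt = default_phantom
        assert dice_masks(default_segmentation.lens_L, gt["lens_L"]) >= 0.6
        assert dice_masks(default_segmentation.lens_R, gt["lens_R"]) >= 0.6

    def test_uniform_eye_yields_empty_lens_with_warning(self):
        v = np.full((30, 30, 30), -1000.0, dtype=np.float32)
        idx = np.indices(v.shape)
        d2 = sum((idx[a] - 14.5) ** 2 for a in range(3))
        eye_grid = d2 <= 64.0
        v[eye_grid] = 25.0
        ct = CTVolume(v, GEOM1)
        eye = BinaryMask(eye_grid, GEOM1)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            lens_l, lens_r = segment_lenses(ct, (eye, eye))
        assert lens_l.is_empty() and lens_r.is_empty()
        assert any("lens" in str(w.message) for w in caught)

    def test_largest_bright_patch_wins(self):
        v = np.full((40, 30, 30), -1000.0, dtype=np.float32)
        idx = np.indices(v.shape)
        d2 = sum((idx[a] - c) ** 2 for a, c in zip(range(3), (19.5, 14.5, 14.5)))
        eye_grid = d2 <= 144.0
        v[eye_grid] = 25.0
        v[14:19, 12:17, 13:15] = 125.0  # 50-voxel patch
        v[24:26, 13:18, 14] = 125.0     # 10-voxel patch
        ct = CTVolume(v, GEOM1)
        eye = BinaryMask(eye_grid, GEOM1)
        lens_l, _ = segment_lenses(ct, (eye, eye), SegmentationParams(lens_closing_mm=0.5))
        assert lens_l.voxels[16, 14, 13]
        assert not lens_l.voxels[24, 15, 14]


class TestSegmentAll:
    def test_all_structures_nonempty(self, default_segmentation):
        for name in ("brain", "eye_L", "eye_R", "lens_L", "lens_R"):
            assert not getattr(default_segmentation, name).is_empty()

    def test_deterministic(self, default_phantom, default_segmentation):
        from brainplan.segmentation import segment_all

        ct, _ = default_phantom
        again = segment_all(ct)
        for name in ("brain", "eye_L", "eye_R", "lens_L", "lens_R"):
            assert np.array_equal(getattr(again, name).voxels,
                                  getattr(default_segmentation, name).voxels)

    def test_lens_centroid_near_its_eye(self, default_segmentation):
        for eye, lens in ((default_segmentation.eye_L, default_segmentation.lens_L),
                          (default_segmentation.eye_R, default_segmentation.lens_R)):
            idx = np.argwhere(eye.voxels)
            lo = eye.geometry.indices_to_mm(idx.min(axis=0))[0] - 3.0
            hi = eye.geometry.indices_to_mm(idx.max(axis=0))[0] + 3.0
            c = lens.centroid_mm()
            assert np.all(c >= lo) and np.all(c <= hi)
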