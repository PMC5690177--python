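"""Surface extraction, cropping, translations-only ICP and the
direction-selective RMS similarity score."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from brainplan.matching import (
    CaseDatabase,
    CropPlane,
    SurfaceCloud,
    crop_for_matching,
    icp_align,
    mask_to_surface,
    match_score,
    rank_database,
    score_surfaces,
)
from tests.conftest import make_mask


def lattice_cloud(pitch=15.0, n=10, label="brain"):
    """Flat x-y lattice at z=0; pitch far exceeds the shifts applied in tests,
    so nearest neighbours stay unambiguous."""
    xs, ys = np.meshgrid(np.arange(n) * pitch, np.arange(n) * pitch)
    pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    return SurfaceCloud(pts, np.full(len(pts), label))


class TestMaskToSurface:
    def test_cube_boundary_count(self):
        grid = np.zeros((5, 5, 5), dtype=bool)
        grid[1:4, 1:4, 1:4] = True
        cloud = mask_to_surface(make_mask(grid))
        assert len(cloud) == 26  # all cube voxels except the centre

    def test_sphere_points_near_radius(self):
        idx = np.indices((31, 31, 31))
        d2 = sum((idx[a] - 15.0) ** 2 for a in range(3))
        mask = make_mask(d2 <= 100.0)
        cloud = mask_to_surface(mask)
        r = np.linalg.norm(cloud.points - [15.0, 15.0, 15.0], axis=1)
        assert np.all((r >= 9.0) & (r <= 11.0))

    def test_decimation_is_exact_and_deterministic(self, coarse_phantom):
        _, gt = coarse_phantom
        a = mask_to_surface(gt["brain"], max_points=10, seed=5)
        b = mask_to_surface(gt["brain"], max_points=10, seed=5)
        assert len(a) == 10
        assert np.array_equal(a.points, b.points)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mask_to_surface(make_mask(np.zeros((4, 4, 4), dtype=bool)))


class TestCropForMatching:
    def test_far_plane_keeps_everything(self, coarse_phantom):
        _, gt = coarse_phantom
        structures = {n: gt[n] for n in ("brain", "eye_L", "eye_R")}
        full = crop_for_matching(structures, plane=CropPlane((0.0, 0.0, -1000.0), 0.0))
        default = crop_for_matching(structures)
        n_brain_full = int((full.labels == "brain").sum())
        n_uncropped = len(mask_to_surface(gt["brain"], 2000))
        assert n_brain_full == n_uncropped
        assert int((default.labels == "brain").sum()) < n_brain_full

    def test_centroid_plane_discards_posterior(self, coarse_phantom):
        _, gt = coarse_phantom
        structures = {n: gt[n] for n in ("brain", "eye_L", "eye_R")}
        plane = CropPlane(tuple(gt["brain"].centroid_mm()), 0.0)
        cloud = crop_for_matching(structures, plane=plane)
        brain_pts = cloud.points[cloud.labels == "brain"]
        # every retained brain point satisfies the plane inequality exactly
        eye_c = np.vstack([gt["eye_L"].centroid_mm(), gt["eye_R"].centroid_mm()]).mean(0)
        sign = np.sign(plane.signed_distance(eye_c)[0])
        assert np.all(plane.signed_distance(brain_pts) * sign >= 0)
        assert len(brain_pts) < len(mask_to_surface(gt["brain"], 2000))

    def test_eyes_always_fully_kept(self, coarse_phantom):
        _, gt = coarse_phantom
        structures = {n: gt[n] for n in ("brain", "eye_L", "eye_R")}
        cloud = crop_for_matching(structures)
        for eye in ("eye_L", "eye_R"):
            assert int((cloud.labels == eye).sum()) == len(mask_to_surface(gt[eye], 2000))

    def test_missing_structure_rejected(self, coarse_phantom):
        _, gt = coarse_phantom
        with pytest.raises(ValueError):
            crop_for_matching({"brain": gt["brain"], "eye_L": gt["eye_L"]})


class TestICP:
    def test_identity_alignment(self):
        cloud = lattice_cloud()
        assert np.allclose(icp_align(cloud, cloud), 0.0, atol=1e-12)

    def test_two_point_closed_form(self):
        fixed = SurfaceCloud([[0, 0, 0], [10, 0, 0]], ["a", "a"])
        moving = SurfaceCloud([[3, 2, 1], [13, 2, 1]], ["a", "a"])
        t = icp_align(moving, fixed)
        assert np.allclose(t, [-3.0, -2.0, -1.0], atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_translation_recovery(self, coarse_phantom, seed):
        _, gt = coarse_phantom
        cloud = crop_for_matching({n: gt[n] for n in ("brain", "eye_L", "eye_R")})
        rng = np.random.default_rng(seed)
        true_t = rng.uniform(-30.0, 30.0, 3)
        recovered = icp_align(cloud.translated(true_t), cloud)
        assert np.all(np.abs(recovered + true_t) <= 0.5)

    def test_nonfinite_points_rejected(self):
        with pytest.raises(ValueError):
            SurfaceCloud([[np.nan, 0, 0]], ["a"])


class TestScore:
    def test_self_match_is_zero(self, coarse_phantom):
        _, gt = coarse_phantom
        cloud = crop_for_matching({n: gt[n] for n in ("brain", "eye_L", "eye_R")})
        score, t = match_score(cloud, cloud)
        assert score == 0.0
        assert np.allclose(t, 0.0)

    def test_pure_x_offset_is_invisible(self):
        plate = lattice_cloud()
        shifted = plate.translated([7.0, 0.0, 0.0])
        assert score_surfaces(shifted, plate) == 0.0
        score, _ = match_score(shifted, plate)
        assert score == pytest.approx(0.0, abs=1e-9)

    def test_localized_discrepancy_penalized_over_uniform(self):
        base = lattice_cloud()
        uniform = SurfaceCloud(base.points + [0, 0, 2.0], base.labels)

        local_pts = base.points.copy()
        n = len(local_pts)
        n_bad = n // 10
        local_pts[:n_bad, 2] += 7.0
        local_pts[n_bad:, 2] += 1.0
        localized = SurfaceCloud(local_pts, base.labels)

        s_uniform = score_surfaces(uniform, base)
        s_local = score_surfaces(localized, base)
        frac = n_bad / n
        assert s_uniform == pytest.approx(2.0, abs=1e-9)
        assert s_local == pytest.approx(np.sqrt(frac * 49 + (1 - frac) * 1), abs=1e-9)
        assert s_local > s_uniform

        # a plain mean distance ranks the two the other way round
        def mean_distance(p, q):
            d, _ = cKDTree(q.points).query(p.points)
            return d.mean()

        assert mean_distance(localized, base) < mean_distance(uniform, base)

    def test_empty_cloud_rejected(self):
        plate = lattice_cloud()
        with pytest.raises(ValueError):
            score_surfaces(SurfaceCloud(np.empty((0, 3)), np.empty(0)), plate)


class TestRankDatabase:
    def _db_from_clouds(self, clouds):
        db = CaseDatabase()
        for cid, c in clouds.items():
            db.add_case(cid, c)
        return db

    def test_planted_case_ranks_first_with_zero_score(self, coarse_phantom):
        _, gt = coarse_phantom
        cloud = crop_for_matching({n: gt[n] for n in ("brain", "eye_L", "eye_R")})
        clouds = {f"case{i:02d}": cloud.translated([i + 1.0, -i, 2.0 * i])
                  for i in range(4)}
        # case02 is the patient itself (pure translation is removed by ICP,
        # so every planted translate also scores 0 — perturb the others)
        rng = np.random.default_rng(0)
        for i, (cid, c) in enumerate(clouds.items()):
            if cid != "case02":
                clouds[cid] = SurfaceCloud(
                    c.points + rng.normal(0, 1.5, c.points.shape), c.labels)
        results = rank_database(cloud, self._db_from_clouds(clouds))
        assert results[0].case_id == "case02"
        assert results[0].score == pytest.approx(0.0, abs=1e-9)
        assert all(results[i].score <= results[i + 1].score
                   for i in range(len(results) - 1))

    def test_ties_break_by_case_id(self):
        plate = lattice_cloud()
        db = self._db_from_clouds({"b": plate, "a": plate})
        results = rank_database(plate, db)
        assert [r.case_id for r in results] == ["a", "b"]

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            rank_database(lattice_cloud(), CaseDatabase())

    def test_best_score_monotone_under_growth(self, coarse_phantom):
        _, gt = coarse_phantom
        cloud = crop_for_matching({n: gt[n] for n in ("brain", "eye_L", "eye_R")})
        rng = np.random.default_rng(7)
        clouds = {f"c{i:02d}": SurfaceCloud(
            cloud.points + rng.normal(0, 2.0, cloud.points.shape), cloud.labels)
            for i in range(9)}
        db = self._db_from_clouds(clouds)
        ids = sorted(clouds)
        best = [rank_database(cloud, db.subset(ids[:k]))[0].score for k in (3, 6, 9)]
        assert best[0] >= best[1] >= best[2]

    def test_database_save_load_roundtrip(self, coarse_phantom, tmp_path):
        _, gt = coarse_phantom
        cloud = crop_for_matching({n: gt[n] for n in ("brain", "eye_L", "eye_R")})
        db = self._db_from_clouds({"only": cloud})
        db.save(tmp_path)
        back = CaseDatabase.load(tmp_path)
        assert np.array_equal(back.cases["only"].points, cloud.points)
        assert list(back.cases["only"].labels) == list(cloud.labels)
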