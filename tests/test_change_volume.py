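import numpy as np
import pytest

from mealscan.change_volume import (
    ChangeParams,
    consumed_volume,
    delaunay_xy,
    extract_changed,
    prism_volume,
    project_bottom,
    surface_volume,
    z_origin_correct,
)
from mealscan.geometry import PointCloud, crop_to_disk, depth_to_cloud
from mealscan.segmentation import DegenerateInputError
from mealscan.synthetic import (
    MoundSpec,
    analytic_mound_volume,
    render_depth,
    take_bite,
)

from conftest import make_scene


class TestExtractChanged:
    def test_identical_clouds_empty(self, rng):
        pts = rng.uniform(size=(100, 3))
        cloud = PointCloud(pts)
        assert len(extract_changed(cloud, cloud, 0.001)) == 0

    def test_huge_threshold_empty(self, rng):
        a = PointCloud(rng.uniform(size=(50, 3)))
        b = PointCloud(rng.uniform(size=(50, 3)) + 5)
        assert len(extract_changed(a, b, 1e6)) == 0

    def test_empty_target_returns_all(self, rng):
        a = PointCloud(rng.uniform(size=(20, 3)))
        out = extract_changed(a, PointCloud(np.zeros((0, 3))), 0.01)
        assert len(out) == 20

    def test_mound_extracted_from_emptied_plate(self, intrinsics):
        scene = make_scene([MoundSpec("m", 0, (0.0, 0.0), a=0.03, h=0.02)])
        empty = make_scene([])
        frame_t, labels = render_depth(scene, intrinsics, return_labels=True)
        frame_t1 = render_depth(empty, intrinsics)
        cloud_t = depth_to_cloud(frame_t)
        cloud_t1 = depth_to_cloud(frame_t1)
        # noise-free scene: a small threshold loses only the sliver of
        # mound base whose height is below it
        got = extract_changed(cloud_t, cloud_t1, 0.0003)
        n_mound = int((labels >= 3).sum())
        assert abs(len(got) - n_mound) / n_mound < 0.02


class TestProjectBottom:
    def test_exact_xy_matches_returned(self):
        target = PointCloud([[0, 0, 1.0], [1, 0, 2.0], [0, 1, 3.0]])
        top = PointCloud([[1, 0, 9.0], [0, 1, 9.0]])
        out = project_bottom(top, target)
        assert np.allclose(out.points, [[1, 0, 2.0], [0, 1, 3.0]])

    def test_brute_force_oracle(self, rng):
        top = PointCloud(rng.uniform(size=(500, 3)))
        target = PointCloud(rng.uniform(size=(400, 3)))
        out = project_bottom(top, target)
        for t, b in zip(top.points, out.points):
            d = np.hypot(
                target.points[:, 0] - t[0], target.points[:, 1] - t[1]
            )
            assert np.hypot(b[0] - t[0], b[1] - t[1]) <= d.min() + 1e-12

    def test_single_point_target_repeats(self, rng):
        top = PointCloud(rng.uniform(size=(5, 3)))
        target = PointCloud([[0.5, 0.5, 0.1]])
        out = project_bottom(top, target)
        assert np.allclose(out.points, np.tile([0.5, 0.5, 0.1], (5, 1)))

    def test_empty_target_rejected(self):
        with pytest.raises(DegenerateInputError):
            project_bottom(
                PointCloud([[0, 0, 0]]), PointCloud(np.zeros((0, 3)))
            )


class TestZOriginCorrect:
    def test_direct_difference(self):
        top = PointCloud([[1, 2, 5.0]])
        bottom = PointCloud([[1, 2, 3.0]])
        out = z_origin_correct(top, bottom)
        assert np.allclose(out.points, [[1, 2, 2.0]])

    def test_identical_pairs_zero_height(self, rng):
        cloud = PointCloud(rng.uniform(size=(30, 3)))
        out = z_origin_correct(cloud, cloud)
        assert np.allclose(out.points[:, 2], 0.0)
        assert np.allclose(out.points[:, :2], cloud.points[:, :2])

    def test_count_mismatch_rejected(self):
        with pytest.raises(DegenerateInputError):
            z_origin_correct(
                PointCloud(np.zeros((3, 3))), PointCloud(np.zeros((2, 3)))
            )

    def test_mound_height_field_recovered(self, intrinsics):
        scene = make_scene([MoundSpec("m", 0, (0.0, 0.0), a=0.03, h=0.02)])
        empty = make_scene([])
        frame_t, labels = render_depth(scene, intrinsics, return_labels=True)
        cloud_t = depth_to_cloud(frame_t, mask=labels >= 3)
        cloud_t1 = depth_to_cloud(render_depth(empty, intrinsics))
        bottom = project_bottom(cloud_t, cloud_t1)
        corrected = z_origin_correct(cloud_t, bottom)
        heights = -corrected.points[:, 2]  # camera Z points down at the table
        assert heights.max() == pytest.approx(0.02, abs=5e-4)
        assert heights.min() > -1e-6


class TestDelaunay:
    def test_three_points_one_triangle(self):
        tri = delaunay_xy(PointCloud([[0, 0, 1], [1, 0, 2], [0, 1, 3.0]]))
        assert len(tri.triangles) == 1

    def test_unit_square_two_triangles(self):
        tri = delaunay_xy(
            PointCloud([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]])
        )
        assert len(tri.triangles) == 2
        areas = [
            _tri_area_xy(*tri.vertices[t][:, :2]) for t in tri.triangles
        ]
        assert sum(areas) == pytest.approx(1.0)

    def test_empty_circumcircle_property(self, rng):
        pts = np.column_stack([rng.uniform(size=(200, 2)), rng.uniform(size=200)])
        tri = delaunay_xy(PointCloud(pts))
        xy = pts[:, :2]
        for t in tri.triangles:
            a, b, c = xy[t]
            # circumcenter via perpendicular bisector intersection
            d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
            ux = (
                (a @ a) * (b[1] - c[1])
                + (b @ b) * (c[1] - a[1])
                + (c @ c) * (a[1] - b[1])
            ) / d
            uy = (
                (a @ a) * (c[0] - b[0])
                + (b @ b) * (a[0] - c[0])
                + (c @ c) * (b[0] - a[0])
            ) / d
            center = np.array([ux, uy])
            r = np.linalg.norm(a - center)
            inside = np.linalg.norm(xy - center, axis=1) < r - 1e-9
            inside[t] = False
            assert not inside.any()

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateInputError):
            delaunay_xy(PointCloud([[0, 0, 0], [1, 0, 0]]))
        collinear = np.column_stack(
            [np.linspace(0, 1, 5), np.linspace(0, 2, 5), np.ones(5)]
        )
        with pytest.raises(DegenerateInputError):
            delaunay_xy(PointCloud(collinear))


def _tri_area_xy(a, b, c):
    return abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])) / 2


def quadrature_prism_volume(a, b, c):
    """Independent oracle: integrate the linear height interpolant over
    the projected triangle with the 3-midpoint rule (exact for degree 1)."""
    a, b, c = np.asarray(a), np.asarray(b), np.asarray(c)
    area = _tri_area_xy(a, b, c)
    mids = [(a[2] + b[2]) / 2, (b[2] + c[2]) / 2, (c[2] + a[2]) / 2]
    return area * np.mean(mids)


class TestPrismVolume:
    def test_flat_triangle(self):
        v = prism_volume((0, 0, 3), (1, 0, 3), (0, 1, 3))
        assert v == pytest.approx(1.5)

    def test_zero_heights(self, rng):
        xy = rng.uniform(size=(3, 2))
        pts = [np.append(p, 0.0) for p in xy]
        assert prism_volume(*pts) == 0.0

    def test_quadrature_oracle(self, rng):
        for _ in range(100):
            tri = rng.uniform(-1, 1, (3, 2))
            z = rng.uniform(0, 2, 3)
            pts = [np.append(p, h) for p, h in zip(tri, z)]
            want = quadrature_prism_volume(*pts)
            got = prism_volume(*pts)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-15)

    def test_mean_height_times_area_identity(self, rng):
        tri = rng.uniform(-1, 1, (3, 2))
        z = rng.uniform(0, 5, 3)
        pts = [np.append(p, h) for p, h in zip(tri, z)]
        area = _tri_area_xy(*tri)
        assert prism_volume(*pts) == pytest.approx(z.mean() * area)


class TestSurfaceVolume:
    def test_flat_box(self, rng):
        g = np.linspace(0, 0.1, 40)
        gx, gy = np.meshgrid(g, g)
        pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, 0.02)])
        vol = surface_volume(PointCloud(pts))
        assert vol == pytest.approx(200.0, rel=0.005)

    def test_spherical_cap(self, rng):
        a, h = 0.03, 0.02
        big_r = (a * a + h * h) / (2 * h)
        pts = []
        while len(pts) < 5000:
            xy = rng.uniform(-a, a, 2)
            r2 = xy @ xy
            if r2 <= a * a:
                z = np.sqrt(big_r**2 - r2) - (big_r - h)
                pts.append([xy[0], xy[1], z])
        vol = surface_volume(PointCloud(np.array(pts)))
        assert vol == pytest.approx(analytic_mound_volume(a, h), rel=0.02)

    def test_zero_heights_zero_volume(self, rng):
        pts = np.column_stack([rng.uniform(size=(100, 2)), np.zeros(100)])
        assert surface_volume(PointCloud(pts)) == pytest.approx(0.0)

    def test_xy_translation_invariant(self, rng):
        pts = np.column_stack([rng.uniform(size=(200, 2)), rng.uniform(0, 0.05, 200)])
        v1 = surface_volume(PointCloud(pts))
        v2 = surface_volume(PointCloud(pts + [5.0, -3.0, 0.0]))
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_cubic_scaling(self, rng):
        pts = np.column_stack([rng.uniform(size=(200, 2)), rng.uniform(0, 0.05, 200)])
        v1 = surface_volume(PointCloud(pts))
        v2 = surface_volume(PointCloud(pts * 2.0))
        assert v2 == pytest.approx(8.0 * v1, rel=1e-9)


class TestConsumedVolume:
    def test_identical_frames_zero(self, intrinsics):
        scene = make_scene(
            [MoundSpec("m", 0, (0.0, 0.0), a=0.03, h=0.02)], noise_sigma=0.0
        )
        cloud = crop_to_disk(
            depth_to_cloud(render_depth(scene, intrinsics)), (0, 0), 0.09, 0.02
        )
        res = consumed_volume(cloud, cloud, ChangeParams(register=False))
        assert res.volume_cm3 == 0.0

    def test_single_bite_recovered(self, intrinsics):
        scene = make_scene(
            [MoundSpec("m", 0, (0.0, 0.0), a=0.033, h=0.022)],
            noise_sigma=0.0005,
            seed=5,
        )
        after, removed = take_bite(scene, "m", 0.45)
        c0 = crop_to_disk(
            depth_to_cloud(render_depth(scene, intrinsics, seed=5)),
            (0, 0), 0.09, 0.02,
        )
        c1 = crop_to_disk(
            depth_to_cloud(render_depth(after, intrinsics, seed=6)),
            (0, 0), 0.09, 0.02,
        )
        res = consumed_volume(c0, c1, ChangeParams(dist_thresh=0.002, seed=1))
        assert res.reliable
        assert res.volume_cm3 == pytest.approx(removed, rel=0.10)

    def test_two_bite_conservation(self, intrinsics):
        scene = make_scene(
            [MoundSpec("m", 0, (0.0, 0.0), a=0.033, h=0.025)], noise_sigma=0.0
        )
        mid, r1 = take_bite(scene, "m", 0.5)
        end, r2 = take_bite(mid, "m", 1.0)
        params = ChangeParams(dist_thresh=0.002, register=False)
        crops = [
            crop_to_disk(
                depth_to_cloud(render_depth(s, intrinsics)), (0, 0), 0.09, 0.02
            )
            for s in (scene, mid, end)
        ]
        v01 = consumed_volume(crops[0], crops[1], params).volume_cm3
        v12 = consumed_volume(crops[1], crops[2], params).volume_cm3
        v02 = consumed_volume(crops[0], crops[2], params).volume_cm3
        assert v01 + v12 == pytest.approx(v02, rel=0.10)
        assert v01 + v12 == pytest.approx(r1 + r2, rel=0.10)

    def test_volume_never_negative(self, rng):
        a = PointCloud(rng.uniform(size=(200, 3)) * [0.1, 0.1, 0.01])
        b = PointCloud(rng.uniform(size=(200, 3)) * [0.1, 0.1, 0.01])
        res = consumed_volume(a, b, ChangeParams(register=False, denoise=False))
        assert res.volume_cm3 >= 0.0
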