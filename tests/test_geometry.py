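import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bloomcount.geometry import (PixelRay, TiePointSet, cast_ray,
                                 extract_plot_images, ground_pixel_size,
                                 intersect_ray_cloud, project_point,
                                 projection_error, reprojection_error)
from bloomcount.scene_io import PlotBoundary, PointCloud


# ---------------------------------------------------------------- projection

@pytest.mark.parametrize("depth", [0.5, 3.0, 14.9])
def test_point_on_optical_axis_hits_principal_point(nadir_view, depth):
    v = nadir_view(position=(2.0, 3.0, 15.0))
    pix = project_point(v, (2.0, 3.0, 15.0 - depth))
    assert pix == pytest.approx(v.principal_point)


def test_point_behind_camera_is_none(nadir_view):
    v = nadir_view()
    assert project_point(v, (0.0, 0.0, 16.0)) is None
    assert project_point(v, v.position) is None  # zero depth


def _make_nadir_view():
    from bloomcount.scene_io import CameraView
    from bloomcount.synthfield import NADIR_ROTATION

    return CameraView("V", 800, 600, 18.0, 0.0038, (299.5, 399.5),
                      np.array([0.0, 0.0, 15.0]), NADIR_ROTATION.copy())


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.tuples(st.floats(-3, 3), st.floats(-2, 2), st.floats(0.1, 14.0)))
def test_project_then_cast_ray_passes_through_point(xyz):
    v = _make_nadir_view()
    p = np.array([xyz[0], xyz[1], 15.0 - xyz[2]])
    pix = project_point(v, p)
    if pix is None or not (0 <= pix[0] < v.height and 0 <= pix[1] < v.width):
        return
    ray = cast_ray(v, pix)
    t = (p - ray.origin) @ ray.direction
    assert np.linalg.norm(p - (ray.origin + t * ray.direction)) < 1e-6


def test_cast_principal_point_is_optical_axis(nadir_view):
    v = nadir_view()
    ray = cast_ray(v, v.principal_point)
    assert np.allclose(ray.direction, [0, 0, -1])  # nadir camera looks down


def test_cast_ray_out_of_bounds_raises(nadir_view):
    with pytest.raises(ValueError):
        cast_ray(nadir_view(), (-1, 10))
    with pytest.raises(ValueError):
        cast_ray(nadir_view(width=100, height=80), (80, 10))


def test_distinct_pixels_give_nonparallel_rays(nadir_view):
    v = nadir_view()
    r1 = cast_ray(v, (100, 100))
    r2 = cast_ray(v, (100, 101))
    assert np.linalg.norm(np.cross(r1.direction, r2.direction)) > 0


def test_pixel_ray_requires_unit_direction():
    with pytest.raises(ValueError):
        PixelRay(origin=np.zeros(3), direction=np.array([0, 0, 2.0]))


# ------------------------------------------------------- ray/cloud intersect

def _down_ray(x=0.0, y=0.0):
    return PixelRay(origin=np.array([x, y, 15.0]),
                    direction=np.array([0.0, 0.0, -1.0]))


def test_point_on_ray_is_hit():
    hit = intersect_ray_cloud(_down_ray(), PointCloud([[0, 0, 1.0]]))
    assert hit.is_hit and hit.distance < 1e-12
    assert np.allclose(hit.point, [0, 0, 1.0])


def test_closest_point_wins_and_fallback_flagged():
    cloud = PointCloud([[0.01, 0, 1.0], [0.5, 0, 1.0]])
    hit = intersect_ray_cloud(_down_ray(), cloud, hit_radius=0.05)
    assert hit.index == 0 and hit.is_hit
    far = intersect_ray_cloud(_down_ray(x=5.0), cloud, hit_radius=0.05)
    assert not far.is_hit  # closest-point fallback, flagged


def test_intersection_matches_brute_force_scan():
    rng = np.random.default_rng(7)
    cloud = PointCloud(rng.uniform(-5, 5, (1000, 3)))
    for _ in range(20):
        origin = rng.uniform(-1, 1, 3) + [0, 0, 10]
        target = cloud.points[rng.integers(1000)] + rng.normal(0, 0.5, 3)
        d = target - origin
        ray = PixelRay(origin=origin, direction=d / np.linalg.norm(d))
        hit = intersect_ray_cloud(ray, cloud)
        rel = cloud.points - ray.origin
        t = rel @ ray.direction
        dist = np.linalg.norm(rel - np.outer(t, ray.direction), axis=1)
        dist[t <= 0] = np.inf
        assert hit.index == int(np.argmin(dist))


def test_empty_cloud_and_all_behind():
    with pytest.raises(ValueError):
        intersect_ray_cloud(_down_ray(), PointCloud(np.empty((0, 3))))
    assert intersect_ray_cloud(_down_ray(), PointCloud([[0, 0, 16.0]])) is None


# ------------------------------------------------------------ plot extraction

def _square_plot(pid, cx, cy, half):
    return PlotBoundary(pid, np.array([
        [cx - half, cy - half, 0], [cx + half, cy - half, 0],
        [cx + half, cy + half, 0], [cx - half, cy + half, 0]], float))


def test_extract_plot_images_coverage_rules(nadir_view):
    v = nadir_view(width=800, height=600)
    footprint_x = 800 * 15.0 * 0.0038 / 18.0  # ~2.5 m
    inside = _square_plot("full", 0.0, 0.0, 0.5)
    # shifted so only one column of vertices projects inside
    partial = _square_plot("part", footprint_x / 2 - 0.01, 0.0, 0.5)
    gone = _square_plot("gone", footprint_x * 2, 0.0, 0.5)
    records = extract_plot_images([v], [inside, partial, gone])
    by_id = {r.plot_id: r for r in records}
    assert by_id["full"].coverage == "full"
    assert all(p is not None for p in by_id["full"].vertex_pixels)
    assert by_id["part"].coverage == "partial"
    assert sum(p is not None for p in by_id["part"].vertex_pixels) == 2
    assert "gone" not in by_id
    r0, c0, r1, c1 = by_id["part"].crop
    assert 0 <= r0 < r1 <= v.height and 0 <= c0 < c1 <= v.width


def test_extract_never_emits_below_two_vertices(nadir_view):
    rng = np.random.default_rng(3)
    v = nadir_view()
    plots = [_square_plot(f"p{i}", rng.uniform(-4, 4), rng.uniform(-4, 4), 0.5)
             for i in range(40)]
    for rec in extract_plot_images([v], plots):
        assert sum(p is not None for p in rec.vertex_pixels) >= 2


# ------------------------------------------------------------------- scale

def test_ground_pixel_size_at_campaign_settings():
    # 18 mm lens at 15 m with a 3.8 um pitch sensor -> ~3.17 mm/px
    assert ground_pixel_size(18.0, 15.0, 0.0038) == pytest.approx(3.17, rel=0.03)


def test_ground_pixel_size_inverse_proportionality():
    base = ground_pixel_size(20.0, 15.0, 0.0038)
    assert ground_pixel_size(40.0, 15.0, 0.0038) == pytest.approx(base / 2)
    # recover the pitch that yields a target GSD by inversion
    pitch = 2.23 * 20.0 / (15.0 * 1000.0)
    assert ground_pixel_size(20.0, 15.0, pitch) == pytest.approx(2.23)


def test_ground_pixel_size_rejects_nonpositive():
    with pytest.raises(ValueError):
        ground_pixel_size(0.0, 15.0, 0.0038)


# --------------------------------------------------------- tie point errors

def _tie_set(view, rng, n, noise=0.0):
    # keep the points well inside the view's ~2.5 x 1.9 m footprint
    half_x = 0.4 * view.width * view.pixel_pitch / view.focal_length * 15.0
    half_y = 0.4 * view.height * view.pixel_pitch / view.focal_length * 15.0
    pts = np.column_stack([rng.uniform(-half_x, half_x, n),
                           rng.uniform(-half_y, half_y, n),
                           rng.uniform(0, 1, n)])
    obs = []
    for i, p in enumerate(pts):
        pix = project_point(view, p)
        pix = (pix[0] + rng.normal(0, noise), pix[1] + rng.normal(0, noise)) \
            if noise else pix
        obs.append((0, i, pix))
    return TiePointSet(tie_points=pts, observations=obs)


def test_reprojection_error_zero_for_exact_projection(nadir_view):
    v = nadir_view()
    tie = _tie_set(v, np.random.default_rng(0), 50)
    errs, mean = reprojection_error([v], tie)
    assert np.abs(errs).max() < 1e-9 and mean < 1e-9


def test_reprojection_error_3_4_5(nadir_view):
    v = nadir_view()
    p = np.array([0.5, 0.5, 1.0])
    pix = project_point(v, p)
    tie = TiePointSet(tie_points=p[None],
                      observations=[(0, 0, (pix[0] + 3, pix[1] + 4))])
    errs, mean = reprojection_error([v], tie)
    assert errs[0] == pytest.approx(5.0) and mean == pytest.approx(5.0)


def test_reprojection_error_matches_rayleigh_mean(nadir_view):
    # isotropic N(0, 0.5 px) per axis -> mean distance = 0.5 sqrt(pi/2)
    v = nadir_view(width=4000, height=3000)
    tie = _tie_set(v, np.random.default_rng(5), 10_000, noise=0.5)
    _, mean = reprojection_error([v], tie)
    assert mean == pytest.approx(0.5 * np.sqrt(np.pi / 2), rel=0.1)


def test_projection_error_zero_on_cloud_of_tie_points(nadir_view):
    v = nadir_view()
    tie = _tie_set(v, np.random.default_rng(1), 30)
    errs = projection_error([v], tie, PointCloud(tie.tie_points))
    for axis in ("easting", "northing", "elevation", "magnitude"):
        assert np.abs(errs[axis]).max() < 1e-9


def test_projection_error_sees_constructed_elevation_offset(nadir_view):
    v = nadir_view()
    tie = _tie_set(v, np.random.default_rng(2), 30)
    shifted = PointCloud(tie.tie_points + [0, 0, 0.02])
    errs = projection_error([v], tie, shifted, hit_radius=0.1)
    # a nadir ray through the tie point hits the shifted copy of the
    # same point, 2 cm higher
    assert np.mean(errs["elevation"]) == pytest.approx(0.02, abs=0.005)
    assert np.allclose(errs["magnitude"],
                       np.sqrt(errs["easting"] ** 2 + errs["northing"] ** 2
                               + errs["elevation"] ** 2))
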