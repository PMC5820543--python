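"""Pinhole projection, pixel-ray casting, plot-image extraction and
tie-point error metrics.

The camera model is an ideal pinhole (no lens distortion): a world point
``p`` maps through ``p_cam = R (p - C)`` and, for positive depth
``p_cam[2]``,

    col = c_col + (f / pitch) * p_cam[0] / p_cam[2]
    row = c_row + (f / pitch) * p_cam[1] / p_cam[2]

Lens distortion, if ever needed, would plug in between the normalized
camera coordinates and the pixel mapping above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .scene_io import CameraView, PlotBoundary, PointCloud

__all__ = [
    "PixelRay",
    "PlotImageRecord",
    "TiePointSet",
    "RayHit",
    "project_point",
    "project_points",
    "cast_ray",
    "intersect_ray_cloud",
    "extract_plot_images",
    "ground_pixel_size",
    "reprojection_error",
    "projection_error",
]


@dataclass(frozen=True)
class PixelRay:
    """A world-frame ray through the camera center and one pixel."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("ray direction must be a unit vector")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class PlotImageRecord:
    """One (raw image, plot) pair whose plot is at least partly visible.

    ``vertex_pixels`` holds the projected ``(row, col)`` of each of the
    4 boundary vertices, ``None`` where the vertex falls outside the
    image (or behind the camera).  ``crop`` is the axis-aligned integer
    bounding box of the in-image vertices, clipped to the image:
    ``(row0, col0, row1, col1)`` with exclusive upper bounds.
    """

    image_id: str
    plot_id: str
    vertex_pixels: tuple
    coverage: str  # "full" | "partial"
    crop: tuple[int, int, int, int]


@dataclass(frozen=True)
class TiePointSet:
    """Sparse-cloud tie points with their per-image feature observations.

    ``observations`` is a list of ``(view_index, tie_index, (row, col))``.
    """

    tie_points: np.ndarray
    observations: list

    def __post_init__(self):
        tp = np.asarray(self.tie_points, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "tie_points", tp)


@dataclass(frozen=True)
class RayHit:
    """Result of a ray/point-cloud intersection.

    ``is_hit`` is True when the perpendicular distance of the returned
    cloud point from the ray is within the hit radius; otherwise the
    closest point is still returned (closest-point fallback) but flagged.
    """

    point: np.ndarray
    index: int
    distance: float
    is_hit: bool


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def project_point(view: CameraView, p) -> tuple[float, float] | None:
    """Project a world point to ``(row, col)``; ``None`` when the point
    is at or behind the camera plane."""
    pix, valid = project_points(view, np.asarray(p, dtype=float).reshape(1, 3))
    if not valid[0]:
        return None
    return (float(pix[0, 0]), float(pix[0, 1]))


def project_points(view: CameraView, pts: np.ndarray):
    """Vectorized projection of ``N x 3`` world points.

    Returns ``(pixels, in_front)`` where ``pixels`` is ``N x 2`` of
    ``(row, col)`` (NaN for points not in front) and ``in_front`` is a
    boolean mask (strictly positive depth).
    """
    pts = np.asarray(pts, dtype=float).reshape(-1, 3)
    cam = (pts - view.position) @ view.rotation.T
    depth = cam[:, 2]
    in_front = depth > 0
    pix = np.full((len(pts), 2), np.nan)
    f = view.focal_px
    with np.errstate(divide="ignore", invalid="ignore"):
        pix[in_front, 1] = view.principal_point[1] + f * cam[in_front, 0] / depth[in_front]
        pix[in_front, 0] = view.principal_point[0] + f * cam[in_front, 1] / depth[in_front]
    return pix, in_front


def cast_ray(view: CameraView, pixel) -> PixelRay:
    """Back-project a pixel ``(row, col)`` into a world-frame ray."""
    row, col = float(pixel[0]), float(pixel[1])
    if not (0 <= row < view.height and 0 <= col < view.width):
        raise ValueError(f"pixel {pixel} outside image bounds "
                         f"({view.height} x {view.width})")
    f = view.focal_px
    d_cam = np.array([(col - view.principal_point[1]) / f,
                      (row - view.principal_point[0]) / f,
                      1.0])
    d_world = view.rotation.T @ d_cam
    d_world /= np.linalg.norm(d_world)
    return PixelRay(origin=view.position.copy(), direction=d_world)


def intersect_ray_cloud(ray: PixelRay, cloud: PointCloud,
                        hit_radius: float = 0.05) -> RayHit | None:
    """Closest cloud point to the ray among points in front of the origin.

    Mirrors the photogrammetry behavior of returning the nearest point
    to the image ray when the ray misses the cloud: the minimum-distance
    point is always returned, flagged ``is_hit`` only when its
    perpendicular distance is within ``hit_radius``.  Returns ``None``
    when every point lies behind the ray origin.
    """
    if len(cloud) == 0:
        raise ValueError("cannot intersect a ray with an empty point cloud")
    rel = cloud.points - ray.origin
    t = rel @ ray.direction
    front = t > 0
    if not front.any():
        return None
    perp = rel[front] - np.outer(t[front], ray.direction)
    dist = np.linalg.norm(perp, axis=1)
    k = int(np.argmin(dist))
    idx = int(np.flatnonzero(front)[k])
    d = float(dist[k])
    return RayHit(point=cloud.points[idx].copy(), index=idx, distance=d,
                  is_hit=d <= hit_radius)


# ---------------------------------------------------------------------------
# plot-image extraction
# ---------------------------------------------------------------------------


def extract_plot_images(views: Sequence[CameraView],
                        boundaries: Sequence[PlotBoundary]) -> list[PlotImageRecord]:
    """Project each plot quadrangle into each view and record coverage.

    A record is emitted only when at least 2 of the 4 projected vertices
    land inside the image; coverage is ``full`` if and only if all 4 do.
    The crop rectangle is the clipped bounding box of the in-image
    vertices.
    """
    records = []
    for view in views:
        for b in boundaries:
            pix, in_front = project_points(view, b.vertices)
            inside = in_front & (pix[:, 0] >= 0) & (pix[:, 0] < view.height) \
                              & (pix[:, 1] >= 0) & (pix[:, 1] < view.width)
            n_in = int(inside.sum())
            if n_in < 2:
                continue
            vp = tuple(
                (float(pix[i, 0]), float(pix[i, 1])) if inside[i] else None
                for i in range(4)
            )
            rows = pix[inside, 0]
            cols = pix[inside, 1]
            r0 = int(np.clip(np.floor(rows.min()), 0, view.height - 1))
            c0 = int(np.clip(np.floor(cols.min()), 0, view.width - 1))
            r1 = int(np.clip(np.ceil(rows.max()) + 1, r0 + 1, view.height))
            c1 = int(np.clip(np.ceil(cols.max()) + 1, c0 + 1, view.width))
            records.append(
                PlotImageRecord(
                    image_id=view.image_id,
                    plot_id=b.plot_id,
                    vertex_pixels=vp,
                    coverage="full" if n_in == 4 else "partial",
                    crop=(r0, c0, r1, c1),
                )
            )
    return records


def plot_records_to_frame(records: Iterable[PlotImageRecord]):
    """Tabulate plot-image records (CSV-ready: one row per record,
    empty vertex cells when the vertex is outside the image)."""
    import pandas as pd

    rows = []
    for r in records:
        row = {"image_id": r.image_id, "plot_id": r.plot_id}
        for i, vp in enumerate(r.vertex_pixels, start=1):
            row[f"v{i}_row"] = np.nan if vp is None else vp[0]
            row[f"v{i}_col"] = np.nan if vp is None else vp[1]
        row["coverage"] = r.coverage
        rows.append(row)
    cols = ["image_id", "plot_id"] + [f"v{i}_{ax}" for i in range(1, 5)
                                      for ax in ("row", "col")] + ["coverage"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# scale arithmetic and tie-point error metrics
# ---------------------------------------------------------------------------


def ground_pixel_size(focal_length: float, height: float, pixel_pitch: float) -> float:
    """Ground sample distance in mm/pixel for a nadir camera.

    ``focal_length`` and ``pixel_pitch`` in mm, flight ``height`` in m.
    """
    if focal_length <= 0 or height <= 0 or pixel_pitch <= 0:
        raise ValueError("focal length, height and pixel pitch must be positive")
    return pixel_pitch * height * 1000.0 / focal_length


def reprojection_error(views: Sequence[CameraView], tie: TiePointSet):
    """Pixel distance between each tie point's projection and its
    original feature observation.  Returns ``(per_observation, mean)``."""
    errs = []
    for view_idx, tie_idx, pixel in tie.observations:
        proj = project_point(views[view_idx], tie.tie_points[tie_idx])
        if proj is None:
            raise ValueError(f"tie point {tie_idx} behind camera {view_idx}")
        errs.append(np.hypot(proj[0] - pixel[0], proj[1] - pixel[1]))
    errs = np.asarray(errs)
    return errs, float(errs.mean()) if len(errs) else float("nan")


def projection_error(views: Sequence[CameraView], tie: TiePointSet,
                     cloud: PointCloud, hit_radius: float = 0.05):
    """Metric error of ray/cloud projection against the tie points.

    For each feature observation the pixel ray is intersected with the
    dense cloud and the returned point compared with the tie point.
    Returns a dict of arrays: signed per-axis differences ``easting``,
    ``northing``, ``elevation`` and the 3D ``magnitude``.
    """
    diffs = []
    for view_idx, tie_idx, pixel in tie.observations:
        ray = cast_ray(views[view_idx], pixel)
        hit = intersect_ray_cloud(ray, cloud, hit_radius=hit_radius)
        if hit is None:
            diffs.append([np.nan, np.nan, np.nan])
            continue
        diffs.append(hit.point - tie.tie_points[tie_idx])
    diffs = np.asarray(diffs, dtype=float).reshape(-1, 3)
    return {
        "easting": diffs[:, 0],
        "northing": diffs[:, 1],
        "elevation": diffs[:, 2],
        "magnitude": np.linalg.norm(diffs, axis=1),
    }
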