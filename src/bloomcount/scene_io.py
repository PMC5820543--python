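"""Data model and readers/writers for the bloom-counting pipeline.

Conventions used throughout the package:

* Pixel coordinates are 0-based ``(row, col)`` with the origin at the
  top-left of the image.
* The world frame is a local metric frame: ``(easting, northing,
  elevation)`` in meters.  No geodetic transforms are performed.
* Point clouds are exchanged as PLY (ASCII or binary little-endian);
  camera views as JSON; plot boundaries and bloom tables as CSV.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

__all__ = [
    "CameraView",
    "PointCloud",
    "PlotBoundary",
    "DetectedBloom",
    "read_point_cloud",
    "write_point_cloud",
    "read_views",
    "write_views",
    "read_boundaries",
    "write_boundaries",
    "read_bloom_table",
    "write_bloom_table",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraView:
    """Intrinsics and pose of one raw aerial image.

    ``rotation`` maps world-frame directions into the camera frame; the
    camera looks along its +z axis, +x maps to increasing column and +y
    to increasing row.  ``principal_point`` is ``(row, col)`` in pixels.
    ``focal_length`` and ``pixel_pitch`` are in millimeters, so
    ``focal_px = focal_length / pixel_pitch``.
    """

    image_id: str
    width: int
    height: int
    focal_length: float
    pixel_pitch: float
    principal_point: tuple[float, float]
    position: np.ndarray
    rotation: np.ndarray

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_pitch <= 0 or self.focal_length <= 0:
            raise ValueError("focal length and pixel pitch must be positive")
        pos = np.asarray(self.position, dtype=float).reshape(3)
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(rot)):
            raise ValueError("camera pose must be finite")
        if np.abs(rot @ rot.T - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation must be orthonormal (R R^T = I within 1e-8)")
        if np.linalg.det(rot) < 0:
            raise ValueError("rotation must be proper (det +1), got a reflection")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "rotation", rot)

    @property
    def focal_px(self) -> float:
        return self.focal_length / self.pixel_pitch


@dataclass(frozen=True)
class PointCloud:
    """N x 3 metric point set with optional per-point RGB colors."""

    points: np.ndarray
    colors: np.ndarray | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        object.__setattr__(self, "points", pts)
        if self.colors is not None:
            col = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(col) != len(pts):
                raise ValueError("colors must match points")
            object.__setattr__(self, "colors", col)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class PlotBoundary:
    """One plot's quadrangle boundary: 4 ordered metric vertices."""

    plot_id: str
    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float).reshape(4, 3)
        # shoelace area in the easting-northing plane
        x, y = v[:, 0], v[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        if area <= 0:
            raise ValueError(f"plot {self.plot_id}: degenerate quadrangle (area 0)")
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        v = self.vertices
        x, y = v[:, 0], v[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass(frozen=True)
class DetectedBloom:
    """A classified bloom candidate.

    ``pixel`` is the blob center ``(row, col)`` in raw-image coordinates.
    ``position3d`` is the ray/point-cloud intersection in meters, or
    ``None`` while the detection has not been (or cannot be) projected.
    """

    image_id: str
    pixel: tuple[float, float]
    position3d: np.ndarray | None = None
    classifier_score: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.classifier_score <= 1.0):
            raise ValueError("classifier score must be in [0, 1]")
        if self.position3d is not None:
            p = np.asarray(self.position3d, dtype=float).reshape(3)
            object.__setattr__(self, "position3d", p)


# ---------------------------------------------------------------------------
# point clouds (PLY)
# ---------------------------------------------------------------------------


def read_point_cloud(path: str | Path) -> PointCloud:
    """Load a PLY point cloud (ASCII or binary little-endian).

    Raises :class:`FormatError` if the vertex element lacks x/y/z, and
    ``IOError`` on truncated files.
    """
    path = Path(path)
    try:
        obj = trimesh.load(str(path), file_type="ply", process=False)
    except Exception as exc:  # trimesh raises a zoo of exception types
        raise FormatError(f"{path}: not a readable PLY file ({exc})") from exc
    verts = np.asarray(getattr(obj, "vertices", np.empty((0, 3))), dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 3:
        raise FormatError(f"{path}: PLY vertex element lacks x/y/z properties")
    colors = None
    raw = getattr(obj, "colors", None)
    if raw is not None and len(raw) == len(verts):
        colors = np.asarray(raw)[:, :3].astype(np.uint8)
    return PointCloud(points=verts, colors=colors)


def write_point_cloud(cloud: PointCloud, path: str | Path, binary: bool = True) -> None:
    """Write a PLY file with float64 coordinates (lossless round-trip)."""
    path = Path(path)
    n = len(cloud)
    has_color = cloud.colors is not None
    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0", f"element vertex {n}"]
    header += [f"property double {ax}" for ax in "xyz"]
    if has_color:
        header += [f"property uchar {c}" for c in ("red", "green", "blue")]
    header += ["end_header"]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            if has_color:
                rec = np.empty(
                    n,
                    dtype=[("x", "<f8"), ("y", "<f8"), ("z", "<f8"),
                           ("r", "u1"), ("g", "u1"), ("b", "u1")],
                )
                rec["x"], rec["y"], rec["z"] = cloud.points.T
                rec["r"], rec["g"], rec["b"] = cloud.colors.T
            else:
                rec = np.empty(n, dtype=[("x", "<f8"), ("y", "<f8"), ("z", "<f8")])
                rec["x"], rec["y"], rec["z"] = cloud.points.T
            fh.write(rec.tobytes())
        else:
            buf = io.StringIO()
            for i in range(n):
                x, y, z = (float(c) for c in cloud.points[i])
                line = f"{x!r} {y!r} {z!r}"
                if has_color:
                    r, g, b = cloud.colors[i]
                    line += f" {r} {g} {b}"
                buf.write(line + "\n")
            fh.write(buf.getvalue().encode("ascii"))


# ---------------------------------------------------------------------------
# camera views (JSON)
# ---------------------------------------------------------------------------


def _orthonormalize(rot: np.ndarray) -> np.ndarray:
    """Project a nearly-orthonormal matrix onto SO(3) (nearest rotation)."""
    u, _, vt = np.linalg.svd(rot)
    r = u @ vt
    if np.linalg.det(r) < 0:
        raise ValueError("rotation has determinant -1 (reflection), invalid pose")
    return r


def read_views(path: str | Path) -> list[CameraView]:
    """Read camera views from a JSON file (list of per-image records).

    Rotations within 1e-3 of orthonormal are snapped to the nearest
    rotation; anything worse (or a reflection) raises ``ValueError``.
    """
    with open(path) as fh:
        records = json.load(fh)
    views = []
    for rec in records:
        rot = np.asarray(rec["rotation"], dtype=float).reshape(3, 3)
        dev = np.abs(rot @ rot.T - np.eye(3)).max()
        if dev > 1e-3:
            raise ValueError(
                f"view {rec.get('image_id')}: rotation not orthonormal (deviation {dev:.2e})"
            )
        rot = _orthonormalize(rot)
        views.append(
            CameraView(
                image_id=str(rec["image_id"]),
                width=int(rec["width"]),
                height=int(rec["height"]),
                focal_length=float(rec["focal_length_mm"]),
                pixel_pitch=float(rec["pixel_pitch_mm"]),
                principal_point=(float(rec["principal_point"][0]),
                                 float(rec["principal_point"][1])),
                position=np.asarray(rec["position"], dtype=float),
                rotation=rot,
            )
        )
    return views


def write_views(views: Sequence[CameraView], path: str | Path) -> None:
    records = [
        {
            "image_id": v.image_id,
            "width": v.width,
            "height": v.height,
            "focal_length_mm": v.focal_length,
            "pixel_pitch_mm": v.pixel_pitch,
            "principal_point": list(v.principal_point),
            "position": v.position.tolist(),
            "rotation": v.rotation.tolist(),
        }
        for v in views
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


# ---------------------------------------------------------------------------
# plot boundaries (CSV)
# ---------------------------------------------------------------------------

_BOUNDARY_HEADER = ["plot_id"] + [f"{ax}{i}" for i in range(1, 5) for ax in "xyz"]


def read_boundaries(path: str | Path) -> list[PlotBoundary]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                verts = [[float(row[f"x{i}"]), float(row[f"y{i}"]), float(row[f"z{i}"])]
                         for i in range(1, 5)]
            except (KeyError, TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed boundary row") from exc
            out.append(PlotBoundary(plot_id=row["plot_id"], vertices=np.asarray(verts)))
    return out


def write_boundaries(boundaries: Sequence[PlotBoundary], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_BOUNDARY_HEADER)
        for b in boundaries:
            writer.writerow([b.plot_id] + [repr(float(c)) for c in b.vertices.ravel()])


# ---------------------------------------------------------------------------
# bloom tables (CSV)
# ---------------------------------------------------------------------------

_BLOOM_HEADER = ["image_id", "row", "col", "x", "y", "z", "score"]


def write_bloom_table(blooms: Sequence[DetectedBloom], path: str | Path) -> None:
    """Write detections as CSV; an absent 3D position becomes empty cells."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_BLOOM_HEADER)
        for b in blooms:
            if b.position3d is None:
                xyz = ["", "", ""]
            else:
                xyz = [repr(float(c)) for c in b.position3d]
            writer.writerow([b.image_id, repr(float(b.pixel[0])),
                             repr(float(b.pixel[1])), *xyz,
                             repr(float(b.classifier_score))])


def read_bloom_table(path: str | Path) -> list[DetectedBloom]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _BLOOM_HEADER:
            raise FormatError(f"{path}: unexpected header {reader.fieldnames}")
        for lineno, row in enumerate(reader, start=2):
            try:
                cells = [row[k] for k in _BLOOM_HEADER]
                if any(c is None for c in cells):
                    raise ValueError("short row")
                xyz = [row["x"], row["y"], row["z"]]
                if all(c == "" for c in xyz):
                    pos = None
                elif any(c == "" for c in xyz):
                    raise ValueError("partial 3D position")
                else:
                    pos = np.array([float(c) for c in xyz])
                out.append(
                    DetectedBloom(
                        image_id=row["image_id"],
                        pixel=(float(row["row"]), float(row["col"])),
                        position3d=pos,
                        classifier_score=float(row["score"]),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed bloom row") from exc
    return out
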