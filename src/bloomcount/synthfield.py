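"""Synthetic test-field generator.

Emulates the measurement campaign end to end: a grid of single-plant
plots (default 12 x 11 at 1.5 m spacing), a canopy point cloud sampled
densely enough that every 1.3 cm raster cell is covered, bright bloom
disks on the canopy tops, nadir camera views at 15 m flight height with
the real imaging scale (~3.2 mm ground pixel size), and rendered images
by point splatting.

Cloud incompleteness is modelled by removing contiguous patches of
canopy samples from the *delivered* point cloud; rendered images always
use the full scene, because in a real campaign the photographs show
every bloom — incompleteness is an artifact of the reconstruction, and
it is exactly what makes some detections unprojectable downstream.

The default scene is diffuse-light (no specular highlights); distractor
glints can be enabled to stress the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ground_pixel_size, project_points
from .scene_io import CameraView, PlotBoundary, PointCloud

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "SynthField",
    "generate_field",
    "render_views",
    "generate_patches",
    "COLOR_CANOPY",
    "COLOR_BLOOM",
    "COLOR_GROUND",
]

# shared palette so training patches match rendered imagery
COLOR_CANOPY = np.array([45, 90, 40], dtype=float)
COLOR_GROUND = np.array([110, 90, 65], dtype=float)
COLOR_BLOOM = np.array([245, 243, 235], dtype=float)
COLOR_GLINT = np.array([235, 235, 215], dtype=float)
COLOR_BOLL = np.array([205, 192, 168], dtype=float)

# camera orientation for a nadir shot: +x_cam = east, +y_cam = south
# (row grows southward), +z_cam = down.  Proper rotation (det +1).
NADIR_ROTATION = np.diag([1.0, -1.0, -1.0])


@dataclass(frozen=True)
class FieldSpec:
    """Scene and imaging parameters.

    Layout defaults follow a single-plant-per-plot trial: 12 x 11 plots
    at 1.5 m spacing.  Imaging defaults are a 15 m nadir flight with an
    18 mm lens and 3.8 um pixel pitch, i.e. ~3.17 mm ground pixel size,
    which is the scale at which the screening constants (15 px minimum
    object, 20 px flower diameter, 36 px patch) are meaningful.
    """

    rows: int = 12
    cols: int = 11
    spacing: float = 1.5
    plot_size: float = 1.2
    blooms_per_plot: int | tuple[int, int] = 1
    bloom_radius: float = 0.03
    bloom_min_separation: float = 0.3
    canopy_radius: float = 0.45
    canopy_height: float = 0.8
    canopy_noise: float = 0.02
    cell_size: float = 0.013
    dropout: float = 0.0
    dropout_patch_radius: float = 0.12
    glints_per_plot: int = 0
    flight_height: float = 15.0
    focal_length: float = 18.0
    pixel_pitch: float = 0.0038
    image_shape: tuple[int, int] = (2400, 3200)  # (rows, cols) pixels
    view_overlap: float = 0.6

    def __post_init__(self):
        if min(self.rows, self.cols) < 1:
            raise ValueError("layout must have at least one plot")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        for name in ("spacing", "plot_size", "bloom_radius", "canopy_radius",
                     "canopy_height", "cell_size", "flight_height",
                     "focal_length", "pixel_pitch", "dropout_patch_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.plot_size > self.spacing:
            raise ValueError("plots would overlap: plot_size > spacing")

    @property
    def gsd_mm(self) -> float:
        return ground_pixel_size(self.focal_length, self.flight_height,
                                 self.pixel_pitch)

    @property
    def extent(self) -> tuple[float, float]:
        """Field extent (east, north) in meters including a half-spacing
        margin around the outer plots."""
        return (self.spacing * self.cols, self.spacing * self.rows)

    def plot_center(self, r: int, c: int) -> tuple[float, float]:
        return (self.spacing * (c + 0.5), self.spacing * (r + 0.5))


@dataclass(frozen=True)
class GroundTruth:
    """Per-plot bookkeeping of the generated scene."""

    counts: dict
    positions: dict
    pcc: dict

    def __post_init__(self):
        for pid, cnt in self.counts.items():
            if cnt != len(self.positions.get(pid, ())):
                raise ValueError(f"plot {pid}: count does not match positions")

    @property
    def total_blooms(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SynthField:
    """A generated scene: the delivered (possibly incomplete) cloud,
    the full scene cloud used for rendering, plot boundaries and truth."""

    spec: FieldSpec
    cloud: PointCloud
    scene_cloud: PointCloud
    boundaries: list
    truth: GroundTruth


def _plot_id(r: int, c: int) -> str:
    return f"{r:02d}{c:02d}"


def _sample_region(rng, x0, y0, x1, y1, pitch):
    """Jittered lattice samples of a rectangle; jitter < pitch/4 keeps
    one sample in every pitch-cell, so a half-cell pitch guarantees a
    sample in every raster cell."""
    xs = np.arange(x0 + pitch / 2, x1, pitch)
    ys = np.arange(y0 + pitch / 2, y1, pitch)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    pts += rng.uniform(-pitch / 4, pitch / 4, size=pts.shape)
    return pts


def generate_field(spec: FieldSpec = FieldSpec(), seed: int = 0) -> SynthField:
    """Generate the scene: point cloud, plot boundaries, ground truth.

    Plot interiors are sampled at half the raster cell size (so a
    complete plot rasterizes with zero empty cells); alleys at the cell
    size (rendering only).  Blooms are bright disks sitting on the
    canopy dome; dropout carves contiguous patches out of each plot's
    canopy samples until the requested fraction is removed.
    """
    rng = np.random.default_rng(seed)
    ext_x, ext_y = spec.extent
    half = spec.plot_size / 2.0

    pts_all = []
    cols_all = []
    keep_all = []
    boundaries = []
    counts, positions, pcc = {}, {}, {}

    # alleys: everything outside the plot squares, coarse pitch
    alley = _sample_region(rng, 0, 0, ext_x, ext_y, spec.cell_size)
    cx_idx = np.floor(alley[:, 0] / spec.spacing)
    cy_idx = np.floor(alley[:, 1] / spec.spacing)
    pcx = (cx_idx + 0.5) * spec.spacing
    pcy = (cy_idx + 0.5) * spec.spacing
    in_plot = (np.abs(alley[:, 0] - pcx) <= half) & (np.abs(alley[:, 1] - pcy) <= half)
    alley = alley[~in_plot]
    z = rng.normal(0.0, 0.005, size=len(alley))
    pts_all.append(np.column_stack([alley, z]))
    cols_all.append(COLOR_GROUND + rng.normal(0, 8, size=(len(alley), 3)))
    keep_all.append(np.ones(len(alley), dtype=bool))

    n_blooms_cfg = spec.blooms_per_plot
    for r in range(spec.rows):
        for c in range(spec.cols):
            pid = _plot_id(r, c)
            cx, cy = spec.plot_center(r, c)
            boundaries.append(PlotBoundary(
                plot_id=pid,
                vertices=np.array([
                    [cx - half, cy - half, 0.0],
                    [cx + half, cy - half, 0.0],
                    [cx + half, cy + half, 0.0],
                    [cx - half, cy + half, 0.0],
                ])))

            pts = _sample_region(rng, cx - half, cy - half,
                                 cx + half, cy + half, spec.cell_size / 2.0)
            d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
            canopy = d < spec.canopy_radius
            t = np.clip(d / spec.canopy_radius, 0, 1)
            z = np.where(
                canopy,
                spec.canopy_height * np.sqrt(np.clip(1 - t ** 2, 0, 1))
                + rng.normal(0, spec.canopy_noise, size=len(pts)),
                rng.normal(0.0, 0.005, size=len(pts)))
            colors = np.where(canopy[:, None],
                              COLOR_CANOPY + rng.normal(0, 12, size=(len(pts), 3)),
                              COLOR_GROUND + rng.normal(0, 8, size=(len(pts), 3)))

            # blooms: disks on the canopy dome, mutually separated
            if isinstance(n_blooms_cfg, tuple):
                k = int(rng.integers(n_blooms_cfg[0], n_blooms_cfg[1] + 1))
            else:
                k = int(n_blooms_cfg)
            placed = []
            attempts = 0
            max_r = spec.canopy_radius - spec.bloom_radius - 0.02
            while len(placed) < k and attempts < 500:
                attempts += 1
                ang = rng.uniform(0, 2 * np.pi)
                rad = max_r * np.sqrt(rng.uniform())
                bx, by = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
                if all(np.hypot(bx - px, by - py) >= spec.bloom_min_separation
                       for px, py, _ in placed):
                    tb = rad / spec.canopy_radius
                    bz = spec.canopy_height * np.sqrt(1 - tb ** 2) + 0.02
                    placed.append((bx, by, bz))
            for bx, by, bz in placed:
                m = np.hypot(pts[:, 0] - bx, pts[:, 1] - by) < spec.bloom_radius
                z[m] = bz + rng.normal(0, 0.003, size=int(m.sum()))
                colors[m] = COLOR_BLOOM + rng.normal(0, 4, size=(int(m.sum()), 3))

            # specular glints (off by default: diffuse illumination)
            for _ in range(spec.glints_per_plot):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0.1, 0.85) * spec.canopy_radius
                gx, gy = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
                m = np.hypot(pts[:, 0] - gx, pts[:, 1] - gy) < 0.006
                colors[m] = COLOR_GLINT + rng.normal(0, 4, size=(int(m.sum()), 3))

            # dropout: contiguous patches of canopy samples
            keep = np.ones(len(pts), dtype=bool)
            n_canopy = int(canopy.sum())
            target = int(round(spec.dropout * n_canopy))
            dropped = 0
            while dropped < target:
                ang = rng.uniform(0, 2 * np.pi)
                rad = spec.canopy_radius * np.sqrt(rng.uniform())
                px, py = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
                dist = np.hypot(pts[:, 0] - px, pts[:, 1] - py)
                m = (dist < spec.dropout_patch_radius) & canopy & keep
                idx = np.flatnonzero(m)
                if len(idx) == 0:
                    continue
                need = target - dropped
                if len(idx) > need:
                    # trim the last patch from its rim inward
                    idx = idx[np.argsort(dist[idx])][:need]
                keep[idx] = False
                dropped += len(idx)

            counts[pid] = len(placed)
            positions[pid] = np.array([list(b) for b in placed]).reshape(-1, 3)
            pcc[pid] = 1.0 - (dropped / n_canopy if n_canopy else 0.0)
            pts_all.append(np.column_stack([pts, z]))
            cols_all.append(colors)
            keep_all.append(keep)

    points = np.vstack(pts_all)
    colors = np.clip(np.vstack(cols_all), 0, 255).astype(np.uint8)
    keep = np.concatenate(keep_all)
    scene = PointCloud(points=points, colors=colors)
    delivered = PointCloud(points=points[keep], colors=colors[keep])
    return SynthField(spec=spec, cloud=delivered, scene_cloud=scene,
                      boundaries=boundaries,
                      truth=GroundTruth(counts=counts, positions=positions, pcc=pcc))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def make_views(spec: FieldSpec) -> list[CameraView]:
    """Nadir camera grid covering the field with the configured overlap;
    dense enough that every plot appears in at least three views."""
    h, w = spec.image_shape
    gsd_m = spec.gsd_mm / 1000.0
    foot_x, foot_y = w * gsd_m, h * gsd_m
    ext_x, ext_y = spec.extent
    step_x = foot_x * (1.0 - spec.view_overlap)
    step_y = foot_y * (1.0 - spec.view_overlap)
    nx = max(2, int(np.ceil(ext_x / step_x)) + 1)
    ny = max(2, int(np.ceil(ext_y / step_y)) + 1)
    views = []
    k = 0
    for yc in np.linspace(0.0, ext_y, ny):
        for xc in np.linspace(0.0, ext_x, nx):
            views.append(CameraView(
                image_id=f"IMG_{k:03d}",
                width=w, height=h,
                focal_length=spec.focal_length,
                pixel_pitch=spec.pixel_pitch,
                principal_point=((h - 1) / 2.0, (w - 1) / 2.0),
                position=np.array([xc, yc, spec.flight_height]),
                rotation=NADIR_ROTATION.copy(),
            ))
            k += 1
    return views


def render_views(field: SynthField, views: list[CameraView] | None = None,
                 background: int = 18) -> tuple[dict, list[CameraView]]:
    """Render each view by splatting the full scene cloud.

    Points are painted far-to-near with a square splat sized to close
    the gaps between neighbouring samples at the working ground pixel
    size, so surfaces appear solid and nearer geometry occludes farther
    geometry.  Returns ``(images, views)`` with images keyed by image id.
    """
    spec = field.spec
    if views is None:
        views = make_views(spec)
    pts = field.scene_cloud.points
    colors = field.scene_cloud.colors
    gsd_m = spec.gsd_mm / 1000.0
    splat = int(np.ceil(spec.cell_size / gsd_m)) + 1
    offs = np.arange(splat) - splat // 2

    images = {}
    for view in views:
        img = np.full((view.height, view.width, 3), background, dtype=np.uint8)
        pix, in_front = project_points(view, pts)
        rows = np.round(pix[:, 0]).astype(np.int64, copy=False)
        cols = np.round(pix[:, 1]).astype(np.int64, copy=False)
        pad = splat  # keep splats that touch the frame
        ok = in_front & (rows > -pad) & (rows < view.height + pad) \
                      & (cols > -pad) & (cols < view.width + pad)
        idx = np.flatnonzero(ok)
        depth = (view.position[2] - pts[idx, 2])
        order = idx[np.argsort(-depth, kind="stable")]  # far first
        r0, c0, col = rows[order], cols[order], colors[order]
        for dr in offs:
            rr = r0 + dr
            for dc in offs:
                cc = c0 + dc
                m = (rr >= 0) & (rr < view.height) & (cc >= 0) & (cc < view.width)
                img[rr[m], cc[m]] = col[m]
        images[view.image_id] = img
    return images, views


# ---------------------------------------------------------------------------
# training patches
# ---------------------------------------------------------------------------


def _canopy_texture(rng, size):
    base = COLOR_CANOPY + rng.normal(0, 12, size=(size, size, 3))
    # blocky speckle like splatted points
    coarse = rng.normal(0, 10, size=(size // 4 + 1, size // 4 + 1, 3))
    base += np.kron(coarse, np.ones((4, 4, 1)))[:size, :size]
    return base


def _disk_mask(size, center, radius):
    yy, xx = np.mgrid[:size, :size]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def generate_patches(n_bloom: int, n_nonbloom: int, seed: int = 0,
                     patch_size: int = 36):
    """Labeled 36 x 36 training patches mimicking the rendered imagery.

    Bloom patches are bright near-white disks (7-11 px radius, shaded,
    jittered off-center) on canopy texture.  Non-bloom patches cycle
    through the confusion cases: plain canopy, specular-highlight-like
    small bright blobs, boll-like creamy blobs, and bare ground.
    Returns ``(patches, labels)`` with label 1 = bloom.
    """
    rng = np.random.default_rng(seed)
    patches = np.empty((n_bloom + n_nonbloom, patch_size, patch_size, 3),
                       dtype=np.uint8)
    labels = np.concatenate([np.ones(n_bloom, dtype=np.int64),
                             np.zeros(n_nonbloom, dtype=np.int64)])
    mid = patch_size / 2.0
    for i in range(n_bloom):
        img = _canopy_texture(rng, patch_size)
        center = mid + rng.uniform(-4, 4, size=2)
        radius = rng.uniform(7, 11)
        mask = _disk_mask(patch_size, center, radius)
        shade = rng.uniform(0.85, 1.0)
        img[mask] = COLOR_BLOOM * shade + rng.normal(0, 5, size=(mask.sum(), 3))
        if rng.uniform() < 0.3:  # leaf partly over the flower
            cut = _disk_mask(patch_size, center + rng.uniform(6, 10, size=2),
                             rng.uniform(4, 7))
            img[cut & mask] = COLOR_CANOPY + rng.normal(0, 10, size=((cut & mask).sum(), 3))
        patches[i] = np.clip(img, 0, 255).astype(np.uint8)

    kinds = ["canopy", "glint", "boll", "ground"]
    for j in range(n_nonbloom):
        kind = kinds[j % len(kinds)]
        img = _canopy_texture(rng, patch_size)
        if kind == "glint":
            for _ in range(int(rng.integers(1, 4))):
                c = mid + rng.uniform(-8, 8, size=2)
                mask = _disk_mask(patch_size, c, rng.uniform(1.5, 4.5))
                img[mask] = COLOR_GLINT + rng.normal(0, 6, size=(mask.sum(), 3))
        elif kind == "boll":
            c = mid + rng.uniform(-4, 4, size=2)
            mask = _disk_mask(patch_size, c, rng.uniform(3, 6))
            img[mask] = COLOR_BOLL + rng.normal(0, 8, size=(mask.sum(), 3))
        elif kind == "ground":
            img = COLOR_GROUND + rng.normal(0, 8, size=(patch_size, patch_size, 3))
        patches[n_bloom + j] = np.clip(img, 0, 255).astype(np.uint8)
    return patches, labels


def balanced_patches(n_per_class: int, seed: int = 0):
    """Equal bloom / non-bloom counts (matching the balanced training
    practice)."""
    return generate_patches(n_per_class, n_per_class, seed=seed)
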