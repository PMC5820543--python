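"""Dense point-cloud quality scoring.

An incomplete canopy reconstruction makes blooms unprojectable, so each
plot's cloud is scored before counting: the plot is rasterized into a
2D elevation grid (1.3 cm cells, no interpolation of empty cells), a
ground plane is fitted robustly with MLESAC, cells are split into
ground and canopy by height above that plane, and the point cloud
coverage

    PCC = canopy cells / (canopy cells + empty cells)

is computed.  Empty cells count against coverage because holes in a
planted plot are almost always unreconstructed canopy.  Plots with
PCC below 0.8 are excluded from counting.  Under a coverage ``p`` the
number of missed blooms out of ``n`` follows Binomial(n, 1-p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Polygon

from .scene_io import PlotBoundary, PointCloud

__all__ = [
    "PointCloudGrid",
    "GroundPlane",
    "CountErrorModel",
    "CellLabel",
    "rasterize",
    "fit_ground_mlesac",
    "split_canopy",
    "compute_pcc",
    "pcc_report",
    "filter_plots",
    "expected_miss",
]


class CellLabel:
    OUTSIDE = -1
    EMPTY = 0
    GROUND = 1
    CANOPY = 2


@dataclass(frozen=True)
class PointCloudGrid:
    """2D elevation raster of one plot.

    ``elevation`` is NaN for empty cells; ``inside`` masks cells whose
    center lies inside the plot quadrangle (cells outside do not exist
    for coverage purposes).  ``origin`` is the world (easting, northing)
    of the grid's (0, 0) cell corner; row index increases with northing.
    """

    plot_id: str
    cell_size: float
    elevation: np.ndarray
    inside: np.ndarray
    origin: tuple[float, float]

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    def cell_centers(self):
        """World (easting, northing) of every cell center, shaped like
        the grid with a trailing axis of 2."""
        nr, nc = self.elevation.shape
        e = self.origin[0] + (np.arange(nc) + 0.5) * self.cell_size
        nth = self.origin[1] + (np.arange(nr) + 0.5) * self.cell_size
        ee, nn = np.meshgrid(e, nth)
        return np.stack([ee, nn], axis=-1)


@dataclass(frozen=True)
class GroundPlane:
    """Plane n . x = d with unit normal (oriented upward)."""

    normal: np.ndarray
    offset: float
    inlier_fraction: float

    def __post_init__(self):
        nrm = np.asarray(self.normal, dtype=float).reshape(3)
        if abs(np.linalg.norm(nrm) - 1) > 1e-9:
            raise ValueError("plane normal must be unit length")
        object.__setattr__(self, "normal", nrm)

    def height_at(self, easting, northing):
        """Plane elevation at the given horizontal position(s)."""
        nx, ny, nz = self.normal
        return (self.offset - nx * np.asarray(easting) - ny * np.asarray(northing)) / nz

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Signed point-plane distance."""
        return np.asarray(points) @ self.normal - self.offset


@dataclass(frozen=True)
class CountErrorModel:
    """Binomial model of blooms missed for lack of a valid cloud point."""

    n: int
    p: float

    def __post_init__(self):
        if not (0 <= self.p <= 1):
            raise ValueError("coverage p must be in [0, 1]")
        if self.n < 0:
            raise ValueError("bloom count n must be non-negative")


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def rasterize(cloud: PointCloud, boundary: PlotBoundary,
              cell_size: float = 0.013) -> PointCloudGrid:
    """Rasterize the plot's points into an elevation grid.

    The grid covers the quadrangle's bounding box; a cell exists iff its
    center is inside the quadrangle.  Each existing cell holds the
    maximum elevation of the points falling in it (the canopy top
    surface); cells with no points stay empty (NaN) — no interpolation.
    """
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    poly = Polygon(boundary.vertices[:, :2])
    minx, miny, maxx, maxy = poly.bounds
    nc = max(1, int(np.ceil((maxx - minx) / cell_size)))
    nr = max(1, int(np.ceil((maxy - miny) / cell_size)))
    grid = PointCloudGrid(plot_id=boundary.plot_id, cell_size=cell_size,
                          elevation=np.full((nr, nc), np.nan),
                          inside=np.zeros((nr, nc), dtype=bool),
                          origin=(minx, miny))
    centers = grid.cell_centers()
    inside = shapely.contains_xy(poly, centers[..., 0].ravel(),
                                 centers[..., 1].ravel()).reshape(nr, nc)
    grid.inside[:] = inside

    pts = cloud.points
    if len(pts):
        ix = np.floor((pts[:, 0] - minx) / cell_size).astype(int)
        iy = np.floor((pts[:, 1] - miny) / cell_size).astype(int)
        ok = (ix >= 0) & (ix < nc) & (iy >= 0) & (iy < nr)
        ix, iy, z = ix[ok], iy[ok], pts[ok, 2]
        elev = np.full((nr, nc), -np.inf)
        np.maximum.at(elev, (iy, ix), z)
        filled = np.isfinite(elev) & inside
        grid.elevation[filled] = elev[filled]
    return grid


# ---------------------------------------------------------------------------
# MLESAC ground plane
# ---------------------------------------------------------------------------


def _grid_points(grid: PointCloudGrid) -> np.ndarray:
    centers = grid.cell_centers()
    m = grid.inside & np.isfinite(grid.elevation)
    return np.column_stack([centers[..., 0][m], centers[..., 1][m],
                            grid.elevation[m]])


def fit_ground_mlesac(data, iterations: int = 500, inlier_sigma: float = 0.02,
                      seed: int = 0) -> GroundPlane:
    """Robust ground-plane fit by MLESAC.

    ``data`` is an N x 3 array, a :class:`PointCloud` or a
    :class:`PointCloudGrid` (non-empty cells are used).  Random 3-point
    hypotheses are scored by the negative log-likelihood of a mixture of
    Gaussian inliers (sd ``inlier_sigma``) and uniform outliers over the
    observed elevation span, with the mixing weight re-estimated per
    hypothesis by a short EM fixed point.  The best plane is refined by
    a least-squares fit to its inliers.  Deterministic for a fixed seed.
    """
    if isinstance(data, PointCloudGrid):
        pts = _grid_points(data)
    elif isinstance(data, PointCloud):
        pts = data.points
    else:
        pts = np.asarray(data, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("need at least 3 points to fit a plane")

    rng = np.random.default_rng(seed)
    span = max(float(pts[:, 2].max() - pts[:, 2].min()), 10 * inlier_sigma)
    sig = inlier_sigma
    gauss_norm = 1.0 / (np.sqrt(2 * np.pi) * sig)
    uniform_pdf = 1.0 / span

    best = None
    best_score = np.inf
    degenerate = 0
    for _ in range(iterations):
        sel = rng.choice(len(pts), size=3, replace=False)
        a, b, c = pts[sel]
        nrm = np.cross(b - a, c - a)
        mag = np.linalg.norm(nrm)
        if mag < 1e-12:
            degenerate += 1
            continue
        nrm = nrm / mag
        if nrm[2] < 0:
            nrm = -nrm
        d = pts @ nrm - a @ nrm
        score, _ = _mlesac_score(d, sig, gauss_norm, uniform_pdf)
        if score < best_score:
            best_score = score
            best = (nrm, float(a @ nrm))
    if best is None:
        raise ValueError("all MLESAC samples were degenerate (collinear points)")

    nrm, off = best
    inliers = np.abs(pts @ nrm - off) <= 2.5 * sig
    if inliers.sum() >= 3:
        sub = pts[inliers]
        centroid = sub.mean(axis=0)
        _, _, vt = np.linalg.svd(sub - centroid, full_matrices=False)
        nrm = vt[2]
        if nrm[2] < 0:
            nrm = -nrm
        off = float(centroid @ nrm)
        inliers = np.abs(pts @ nrm - off) <= 2.5 * sig
    return GroundPlane(normal=nrm, offset=off,
                       inlier_fraction=float(inliers.mean()))


def mlesac_score(distances: np.ndarray, inlier_sigma: float,
                 outlier_span: float) -> float:
    """Negative log-likelihood of point-plane distances under the
    MLESAC Gaussian/uniform mixture (exposed for diagnostics)."""
    gauss_norm = 1.0 / (np.sqrt(2 * np.pi) * inlier_sigma)
    score, _ = _mlesac_score(np.asarray(distances, dtype=float),
                             inlier_sigma, gauss_norm, 1.0 / outlier_span)
    return score


def _mlesac_score(d, sig, gauss_norm, uniform_pdf, em_iters: int = 3):
    g = gauss_norm * np.exp(-0.5 * (d / sig) ** 2)
    gamma = 0.5
    for _ in range(em_iters):
        num = gamma * g
        resp = num / (num + (1 - gamma) * uniform_pdf)
        gamma = float(resp.mean())
        gamma = min(max(gamma, 1e-6), 1 - 1e-6)
    lik = gamma * g + (1 - gamma) * uniform_pdf
    return float(-np.log(lik).sum()), gamma


# ---------------------------------------------------------------------------
# canopy split and coverage
# ---------------------------------------------------------------------------


def split_canopy(grid: PointCloudGrid, plane: GroundPlane,
                 height_threshold: float = 0.1) -> np.ndarray:
    """Label each cell ground / canopy / empty (outside cells excluded).

    A non-empty cell is canopy when its elevation is strictly more than
    ``height_threshold`` above the ground plane at the cell center;
    otherwise ground.  Empty cells stay empty.
    """
    centers = grid.cell_centers()
    ground_z = plane.height_at(centers[..., 0], centers[..., 1])
    labels = np.full(grid.elevation.shape, CellLabel.OUTSIDE, dtype=np.int8)
    labels[grid.inside] = CellLabel.EMPTY
    filled = grid.inside & np.isfinite(grid.elevation)
    canopy = filled & (grid.elevation - ground_z > height_threshold)
    labels[filled] = CellLabel.GROUND
    labels[canopy] = CellLabel.CANOPY
    return labels


def compute_pcc(labels: np.ndarray) -> float:
    """Point cloud coverage: canopy / (canopy + empty) cells.

    Defined as 0 when the plot has neither canopy nor empty cells (an
    unvegetated plot); callers can detect that case from the counts.
    """
    canopy = int((labels == CellLabel.CANOPY).sum())
    empty = int((labels == CellLabel.EMPTY).sum())
    if canopy + empty == 0:
        return 0.0
    return canopy / (canopy + empty)


def pcc_report(grids_and_labels, threshold: float = 0.8) -> pd.DataFrame:
    """Per-plot coverage table: plot_id, cell counts, pcc, retained."""
    rows = []
    for grid, labels in grids_and_labels:
        rows.append({
            "plot_id": grid.plot_id,
            "n_canopy": int((labels == CellLabel.CANOPY).sum()),
            "n_ground": int((labels == CellLabel.GROUND).sum()),
            "n_empty": int((labels == CellLabel.EMPTY).sum()),
            "pcc": compute_pcc(labels),
        })
    df = pd.DataFrame(rows, columns=["plot_id", "n_canopy", "n_ground",
                                     "n_empty", "pcc"])
    df["retained"] = df["pcc"] >= threshold
    return df


def filter_plots(pcc_table: pd.DataFrame, threshold: float = 0.8):
    """Exclude plots with coverage strictly below the threshold.

    Returns ``(retained_ids, report)`` where the report lists the
    excluded plots and their coverage values.
    """
    if len(pcc_table) == 0:
        return [], pcc_table.copy()
    keep = pcc_table["pcc"] >= threshold
    retained = list(pcc_table.loc[keep, "plot_id"])
    report = pcc_table.loc[~keep, ["plot_id", "pcc"]].reset_index(drop=True)
    return retained, report


def expected_miss(model: CountErrorModel) -> dict:
    """Mean and distribution of blooms missed under coverage p.

    Missed blooms follow Binomial(n, 1-p): mean n(1-p), relative error
    (1-p); ``distribution`` is the pmf over k = 0..n missed blooms.
    """
    k = np.arange(model.n + 1)
    pmf = stats.binom.pmf(k, model.n, 1.0 - model.p)
    return {
        "mean_missed": model.n * (1.0 - model.p),
        "relative_error": 1.0 - model.p,
        "distribution": pmf,
    }
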