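"""Constrained-clustering bloom registration.

The same bloom is usually detected in several overlapping images, so
detections must be registered (grouped) before counting.  Registration
is a constrained agglomerative clustering of the detections' 3D
positions with a cannot-link constraint: two detections coming from the
same source image are necessarily different blooms and may never share
a cluster.

The cluster distance is a weighted Euclidean distance that down-weights
the elevation axis (the least accurate axis of a multi-view-stereo
reconstruction):

    d(a, b) = sqrt((ax-bx)^2 + (ay-by)^2 + w^2 (az-bz)^2)

with ``w = 0.5`` by default.  Between clusters the distance is taken
between centers when their source-image sets are disjoint and infinite
otherwise.

The merging loop is deterministic: clusters are visited in ascending
index (creation) order; each live cluster is merged into its nearest
eligible cluster when that distance is strictly below the threshold
``lambda``; cluster centers are recomputed only at the end of each full
pass, so merges within a pass use the centers from the previous pass;
the loop stops when a full pass performs no merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon

from .scene_io import PlotBoundary

__all__ = [
    "RegPoint",
    "Cluster",
    "RegistrationConfig",
    "weighted_distance",
    "constrained_distance",
    "register_blooms",
    "bloom_count_per_plot",
]

INFINITE = float("inf")


@dataclass(frozen=True)
class RegPoint:
    """One bloom detection: a 3D position plus its source-image id
    (the cannot-link class)."""

    position: np.ndarray
    class_id: object

    def __post_init__(self):
        p = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(p)):
            raise ValueError("position must be finite")
        object.__setattr__(self, "position", p)


@dataclass(frozen=True)
class Cluster:
    """A registered bloom: member detections, their mean position and
    the set of source images they came from."""

    members: tuple
    center: np.ndarray
    classes: frozenset

    def __post_init__(self):
        if len(self.classes) != len(self.members):
            raise ValueError("cluster violates the cannot-link constraint "
                             "(duplicate source image)")
        object.__setattr__(self, "center",
                           np.asarray(self.center, dtype=float).reshape(3))


@dataclass(frozen=True)
class RegistrationConfig:
    """``merge_threshold`` is the lambda of the merging rule (meters);
    ``elevation_weight`` the w of the weighted distance."""

    merge_threshold: float
    elevation_weight: float = 0.5

    def __post_init__(self):
        if self.merge_threshold <= 0:
            raise ValueError("merge threshold must be positive")
        if self.elevation_weight < 0:
            raise ValueError("elevation weight must be non-negative")


def weighted_distance(a, b, w: float = 0.5) -> float:
    """Elevation-weighted Euclidean distance between two 3D points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    return float(np.sqrt(d[0] ** 2 + d[1] ** 2 + (w * d[2]) ** 2))


def constrained_distance(ci: Cluster, cj: Cluster, w: float = 0.5) -> float:
    """Weighted center distance, or infinity when the clusters share a
    source image (cannot-link)."""
    if ci.classes & cj.classes:
        return INFINITE
    return weighted_distance(ci.center, cj.center, w)


def register_blooms(points: list[RegPoint], cfg: RegistrationConfig):
    """Run the constrained merging loop over the detections.

    Returns ``(assignment, clusters)`` where ``assignment[k]`` is the
    final cluster index of point ``k`` (indices are original creation
    indices, not renumbered) and ``clusters`` maps each live index to a
    :class:`Cluster`.

    Deterministic: visiting order is ascending cluster index and
    distance ties are broken toward the lowest eligible index.
    """
    n = len(points)
    if n < 1:
        raise ValueError("need at least one point")
    pos = np.stack([p.position for p in points])
    class_ids = [p.class_id for p in points]
    uniq = {c: k for k, c in enumerate(dict.fromkeys(class_ids))}
    n_cls = len(uniq)

    z = np.arange(n)
    centers = pos.copy()
    classmat = np.zeros((n, n_cls), dtype=bool)
    classmat[np.arange(n), [uniq[c] for c in class_ids]] = True
    counts = np.ones(n, dtype=np.int64)
    w = cfg.elevation_weight
    lam = cfg.merge_threshold
    w2 = w * w

    while True:
        merged_any = False
        for i in range(n):
            if counts[i] == 0:
                continue
            live = counts > 0
            live[i] = False
            if not live.any():
                continue
            # eligible: live clusters with class sets disjoint from E_i
            conflict = (classmat & classmat[i]).any(axis=1)
            eligible = live & ~conflict
            cand = np.flatnonzero(eligible)
            if len(cand) == 0:
                continue
            d = centers[cand] - centers[i]
            dist = np.sqrt(d[:, 0] ** 2 + d[:, 1] ** 2 + w2 * d[:, 2] ** 2)
            k = int(np.argmin(dist))  # first minimum -> lowest index
            if dist[k] < lam:
                imin = int(cand[k])
                z[z == i] = imin
                classmat[imin] |= classmat[i]
                counts[imin] += counts[i]
                counts[i] = 0
                merged_any = True
        # end of pass: recompute centers as member means, drop empties
        centers = np.zeros_like(centers)
        np.add.at(centers, z, pos)
        nonzero = counts > 0
        centers[nonzero] /= counts[nonzero, None]
        if not merged_any:
            break

    clusters = {}
    for i in np.flatnonzero(counts > 0):
        members = tuple(int(k) for k in np.flatnonzero(z == i))
        clusters[int(i)] = Cluster(
            members=members,
            center=pos[list(members)].mean(axis=0),
            classes=frozenset(class_ids[k] for k in members),
        )
    return z, clusters


def bloom_count_per_plot(clusters, boundaries: list[PlotBoundary]):
    """Assign each cluster center to the plot quadrangle containing it
    (easting-northing plane) and tally counts per plot.

    Returns ``(counts, outside)``: a dict plot_id -> count covering every
    plot (zero included), and the list of cluster indices falling outside
    all plots.  Centers on a shared edge go to the first plot in file
    order.  Overlapping plot polygons are an invalid layout and raise.
    """
    polys = [(b.plot_id, Polygon(b.vertices[:, :2])) for b in boundaries]
    for a in range(len(polys)):
        for b in range(a + 1, len(polys)):
            inter = polys[a][1].intersection(polys[b][1])
            if inter.area > 1e-12:
                raise ValueError(
                    f"plots {polys[a][0]} and {polys[b][0]} overlap; layout invalid")
    counts = {pid: 0 for pid, _ in polys}
    outside = []
    items = clusters.items() if isinstance(clusters, dict) else enumerate(clusters)
    for idx, cluster in items:
        pt = Point(cluster.center[0], cluster.center[1])
        for pid, poly in polys:
            if poly.covers(pt):
                counts[pid] += 1
                break
        else:
            outside.append(idx)
    return counts, outside
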