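"""Brightness screening of plot images for potential cotton blooms.

Blooms are newly opened white flowers and are usually the brightest
objects in a plot image.  Screening works on the CIELAB lightness
channel: threshold the per-image normalized L, drop tiny components,
merge components closer than a flower diameter, and cut a fixed-size
patch around each surviving object for the CNN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2lab
from skimage.measure import label, regionprops

__all__ = ["ScreeningConfig", "CandidatePatch", "screen_candidates"]


@dataclass(frozen=True)
class ScreeningConfig:
    """Screening parameters.

    l_threshold
        Threshold on the L channel after normalization by the image
        maximum; pixels strictly above it are bright-object pixels.
    min_object_px
        Components smaller than this many pixels are treated as noise.
    merge_distance_px
        Components whose centroids are closer than this (about one
        flower diameter at the working ground pixel size) are merged,
        transitively, into one object.
    patch_size_px
        Side of the square patch cut around each object center.
    """

    l_threshold: float = 0.75
    min_object_px: int = 15
    merge_distance_px: float = 20.0
    patch_size_px: int = 36

    def __post_init__(self):
        if not (0 < self.l_threshold <= 1):
            raise ValueError("l_threshold must be in (0, 1]")
        if self.min_object_px < 1:
            raise ValueError("min_object_px must be >= 1")
        if self.patch_size_px < 2 or self.patch_size_px % 2:
            raise ValueError("patch_size_px must be even and >= 2")


@dataclass(frozen=True)
class CandidatePatch:
    """A potential-bloom patch cut from a plot image.

    ``center`` is (row, col) in raw-image coordinates (plot-image
    coordinates plus the crop origin passed by the caller).  ``padded``
    flags patches that ran over the image border and were zero-padded.
    """

    image_id: str
    plot_id: str
    center: tuple[int, int]
    patch: np.ndarray
    padded: bool = False


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _cut_patch(image: np.ndarray, center: tuple[int, int], size: int):
    """Fixed-size crop centered at ``center``, zero-padded at borders."""
    h, w = image.shape[:2]
    half = size // 2
    r0, c0 = center[0] - half, center[1] - half
    r1, c1 = r0 + size, c0 + size
    patch = np.zeros((size, size, image.shape[2]), dtype=image.dtype)
    sr0, sc0 = max(r0, 0), max(c0, 0)
    sr1, sc1 = min(r1, h), min(c1, w)
    padded = (sr0 != r0) or (sc0 != c0) or (sr1 != r1) or (sc1 != c1)
    patch[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = image[sr0:sr1, sc0:sc1]
    return patch, padded


def screen_candidates(plot_image: np.ndarray,
                      config: ScreeningConfig = ScreeningConfig(),
                      image_id: str = "", plot_id: str = "",
                      origin: tuple[int, int] = (0, 0)) -> list[CandidatePatch]:
    """Screen a plot image for potential-bloom locations.

    Steps: CIELAB conversion; L normalized by its maximum over the plot
    image; binary mask of normalized L strictly above the threshold;
    8-connected component labeling; removal of components below the
    minimum pixel count; transitive merging of components whose
    centroids are closer than the merge distance; one fixed-size patch
    per merged object, centered on the merged centroid (pixel-rounded).

    ``origin`` is the (row, col) of the plot image inside its raw image,
    so reported centers are in raw-image coordinates.  An all-black
    image yields an empty list.
    """
    img = np.asarray(plot_image)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise ValueError("plot image must be a non-empty H x W x 3 array")
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)

    lab_l = rgb2lab(img)[:, :, 0]
    lmax = lab_l.max()
    if lmax <= 0:
        return []
    mask = (lab_l / lmax) > config.l_threshold

    labels = label(mask, connectivity=2)
    props = [p for p in regionprops(labels) if p.num_pixels >= config.min_object_px]
    if not props:
        return []

    centroids = np.array([p.centroid for p in props])
    uf = _UnionFind(len(props))
    for i in range(len(props)):
        d = np.linalg.norm(centroids[i + 1:] - centroids[i], axis=1)
        for j in np.flatnonzero(d < config.merge_distance_px):
            uf.union(i, int(i + 1 + j))

    groups: dict[int, list[int]] = {}
    for i in range(len(props)):
        groups.setdefault(uf.find(i), []).append(i)

    out = []
    for members in groups.values():
        # merged centroid = pixel-mean over the union of member components
        n_px = sum(props[i].num_pixels for i in members)
        center = sum(np.asarray(props[i].centroid) * props[i].num_pixels
                     for i in members) / n_px
        rc = (int(round(center[0])), int(round(center[1])))
        patch, padded = _cut_patch(img, rc, config.patch_size_px)
        out.append(
            CandidatePatch(
                image_id=image_id,
                plot_id=plot_id,
                center=(rc[0] + origin[0], rc[1] + origin[1]),
                patch=patch,
                padded=padded,
            )
        )
    out.sort(key=lambda c: c.center)
    return out
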