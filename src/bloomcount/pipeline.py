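"""End-to-end bloom counting: extract plot images, screen, classify,
project, score cloud quality, register, count.

Stages are file-coupled through the CSV/PLY/JSON interfaces of
``scene_io`` so each can be run and inspected in isolation; this module
glues them together in memory and reports per-plot counts for the plots
whose point cloud passed the coverage filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from .geometry import cast_ray, extract_plot_images, intersect_ray_cloud
from .quality import fit_ground_mlesac, pcc_report, rasterize, split_canopy
from .registration import (RegistrationConfig, RegPoint, bloom_count_per_plot,
                           register_blooms)
from .scene_io import (DetectedBloom, read_boundaries, read_point_cloud,
                       read_views)
from .screening import ScreeningConfig, screen_candidates

log = logging.getLogger("bloomcount.pipeline")

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "run_pipeline_objects"]


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run."""

    cloud_path: str
    views_path: str
    plots_path: str
    images_dir: str
    model_path: str | None = None
    screening: ScreeningConfig = dc_field(default_factory=ScreeningConfig)
    registration: RegistrationConfig = dc_field(
        default_factory=lambda: RegistrationConfig(merge_threshold=0.15))
    cell_size: float = 0.013
    height_threshold: float = 0.1
    pcc_threshold: float = 0.8
    hit_radius: float = 0.05
    mlesac_iterations: int = 300
    train_patches_per_class: int = 800
    train_epochs: int = 8
    seed: int = 0

    def __post_init__(self):
        for name in ("cell_size", "height_threshold", "pcc_threshold", "hit_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PipelineReport:
    """Per-plot counts plus the bookkeeping needed to audit a run.

    ``counts`` has one row per plot: plot_id, pcc, retained, and the
    registered bloom count (NaN for excluded plots).  The totals satisfy
    ``n_detections == registered + unprojectable`` and
    ``sum(in-plot counts) + out_of_plot == n_clusters``.
    """

    counts: pd.DataFrame
    n_candidates: int
    n_detections: int
    n_unprojectable: int
    n_clusters: int
    out_of_plot: int
    warnings: tuple = ()


def _dedupe_per_image(detections: list[DetectedBloom],
                      merge_px: float) -> list[DetectedBloom]:
    """Collapse detections of the same blob reached through overlapping
    plot crops of one raw image (keep the highest score)."""
    by_img: dict[str, list[DetectedBloom]] = {}
    for d in detections:
        by_img.setdefault(d.image_id, []).append(d)
    out = []
    for dets in by_img.values():
        dets = sorted(dets, key=lambda d: -d.classifier_score)
        kept: list[DetectedBloom] = []
        for d in dets:
            if all(np.hypot(d.pixel[0] - k.pixel[0], d.pixel[1] - k.pixel[1])
                   >= merge_px for k in kept):
                kept.append(d)
        out.extend(kept)
    return out


def run_pipeline_objects(cloud, views, boundaries, images, model,
                         cfg: PipelineConfig) -> PipelineReport:
    """Run all stages on in-memory objects (see :func:`run_pipeline`)."""
    warnings_out = []
    view_by_id = {v.image_id: v for v in views}

    records = extract_plot_images(views, boundaries)
    log.info("plot-image extraction: %d views x %d plots -> %d records",
             len(views), len(boundaries), len(records))

    candidates = []
    for rec in records:
        img = images[rec.image_id]
        r0, c0, r1, c1 = rec.crop
        candidates.extend(screen_candidates(
            img[r0:r1, c0:c1], cfg.screening,
            image_id=rec.image_id, plot_id=rec.plot_id, origin=(r0, c0)))
    log.info("screening: %d candidate patches", len(candidates))

    detections = clf.classify_patches(model, candidates)
    detections = _dedupe_per_image(detections, cfg.screening.merge_distance_px)
    log.info("classification: %d bloom detections", len(detections))

    projected = []
    n_unprojectable = 0
    for det in detections:
        ray = cast_ray(view_by_id[det.image_id], det.pixel)
        hit = intersect_ray_cloud(ray, cloud, hit_radius=cfg.hit_radius)
        if hit is None or not hit.is_hit:
            n_unprojectable += 1  # no valid cloud point: cannot be counted
            continue
        projected.append(DetectedBloom(image_id=det.image_id, pixel=det.pixel,
                                       position3d=hit.point,
                                       classifier_score=det.classifier_score))
    log.info("projection: %d placed, %d without a valid cloud point",
             len(projected), n_unprojectable)

    grids_labels = []
    for b in boundaries:
        grid = rasterize(cloud, b, cfg.cell_size)
        plane = fit_ground_mlesac(grid, iterations=cfg.mlesac_iterations,
                                  seed=cfg.seed)
        grids_labels.append((grid, split_canopy(grid, plane,
                                                cfg.height_threshold)))
    quality = pcc_report(grids_labels, threshold=cfg.pcc_threshold)
    retained = set(quality.loc[quality["retained"], "plot_id"])
    if not retained:
        warnings_out.append("no plot passed the coverage filter")
    log.info("quality: %d / %d plots retained (PCC >= %.2f)",
             len(retained), len(boundaries), cfg.pcc_threshold)

    if projected:
        points = [RegPoint(position=d.position3d, class_id=d.image_id)
                  for d in projected]
        _, clusters = register_blooms(points, cfg.registration)
        counts, outside = bloom_count_per_plot(clusters, boundaries)
    else:
        clusters, counts, outside = {}, {b.plot_id: 0 for b in boundaries}, []
    log.info("registration: %d clusters, %d outside all plots",
             len(clusters), len(outside))

    table = quality[["plot_id", "pcc", "retained"]].copy()
    table["count"] = [counts[p] if p in retained else np.nan
                      for p in table["plot_id"]]
    return PipelineReport(
        counts=table,
        n_candidates=len(candidates),
        n_detections=len(detections),
        n_unprojectable=n_unprojectable,
        n_clusters=len(clusters),
        out_of_plot=len(outside),
        warnings=tuple(warnings_out),
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Run the full pipeline from files.

    Reads the point cloud, camera views, plot boundaries and raw images
    from the configured paths; loads the classifier from
    ``cfg.model_path``, or trains one on synthetic patches when no model
    is given.  Fails fast with the stage name when an input is missing.
    """
    from PIL import Image

    from .synthfield import balanced_patches

    for stage, path in (("point cloud", cfg.cloud_path),
                        ("camera views", cfg.views_path),
                        ("plot boundaries", cfg.plots_path),
                        ("raw images", cfg.images_dir)):
        if not Path(path).exists():
            raise FileNotFoundError(f"pipeline stage '{stage}': missing {path}")

    cloud = read_point_cloud(cfg.cloud_path)
    views = read_views(cfg.views_path)
    boundaries = read_boundaries(cfg.plots_path)
    images = {}
    for v in views:
        p = Path(cfg.images_dir) / f"{v.image_id}.png"
        if not p.exists():
            raise FileNotFoundError(f"pipeline stage 'raw images': missing {p}")
        images[v.image_id] = np.asarray(Image.open(p).convert("RGB"))

    if cfg.model_path:
        model = clf.load_model(cfg.model_path)
    else:
        log.info("no model given; training on synthetic patches")
        patches, labels = balanced_patches(cfg.train_patches_per_class,
                                           seed=cfg.seed)
        model = clf.build_cnn(seed=cfg.seed)
        clf.train(model, patches, labels,
                  clf.TrainConfig(epochs=cfg.train_epochs, rng_seed=cfg.seed))
    return run_pipeline_objects(cloud, views, boundaries, images, model, cfg)
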