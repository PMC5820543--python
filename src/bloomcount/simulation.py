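"""Artificial-data study of the registration algorithm.

Ten "images" (classes) each contribute 125 distinct points on the
integer grid {0..9}^3; points that share coordinates across classes are
the same true bloom (the ground-truth partition).  Gaussian position
noise of a controlled magnitude is added and the constrained clustering
is scored against the truth over a sigma x lambda sweep.

Noise convention: the position-error *magnitude* (the vector sum of the
three axis errors) has root-mean-square sigma, which means each axis
receives independent Gaussian noise with standard deviation
sigma / sqrt(3).  A normally distributed magnitude is geometrically
impossible, so the RMS reading is the one implemented.

Misclustering (two directions): a point is misclustered w.r.t. a
reference partition when its result cluster contains a point that the
reference places elsewhere — i.e. every member of an impure cluster.
"By reference" scores the clustering against the truth (sensitive to
merging distinct true blooms); "by result" swaps the roles (sensitive
to splitting one bloom across clusters).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .registration import RegPoint, RegistrationConfig, register_blooms

__all__ = [
    "SimConfig",
    "SimDataset",
    "generate_sim_data",
    "misclustered_points",
    "misclustering_rates",
    "run_sweep",
    "threshold_coverage",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings for one artificial dataset."""

    points_per_class: int = 125
    n_classes: int = 10
    coord_max: int = 9  # inclusive; axes draw integers 0..coord_max
    sigma: float = 0.1
    rng_seed: int = 0

    def __post_init__(self):
        n_cells = (self.coord_max + 1) ** 3
        if not (1 <= self.points_per_class <= n_cells):
            raise ValueError(
                f"points_per_class must be in [1, {n_cells}] "
                "(distinct integer triples available)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_classes < 1:
            raise ValueError("need at least one class")


@dataclass(frozen=True)
class SimDataset:
    """``positions`` are the noiseless integer coordinates, ``classes``
    the per-point class (image) ids, ``observations`` the noisy
    positions and ``truth`` the ground-truth cluster label per point
    (points sharing coordinates share a label)."""

    positions: np.ndarray
    classes: np.ndarray
    observations: np.ndarray
    truth: np.ndarray


def generate_sim_data(cfg: SimConfig = SimConfig()) -> SimDataset:
    """Generate one artificial dataset (deterministic given the seed).

    Per class, ``points_per_class`` distinct uniform integer triples are
    drawn by rejection; the ground truth groups identical coordinates
    across classes; per-axis Gaussian noise with sd sigma/sqrt(3) is
    added to every observation.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    side = cfg.coord_max + 1
    positions = []
    classes = []
    for cls in range(cfg.n_classes):
        seen: set[int] = set()
        while len(seen) < cfg.points_per_class:
            trip = rng.integers(0, side, size=3)
            key = int(trip[0] * side * side + trip[1] * side + trip[2])
            if key not in seen:
                seen.add(key)
                positions.append(trip)
                classes.append(cls)
    positions = np.asarray(positions, dtype=np.int64)
    classes = np.asarray(classes, dtype=np.int64)

    keys = positions[:, 0] * side * side + positions[:, 1] * side + positions[:, 2]
    _, truth = np.unique(keys, return_inverse=True)

    noise = rng.normal(0.0, cfg.sigma / np.sqrt(3.0), size=positions.shape)
    return SimDataset(positions=positions, classes=classes,
                      observations=positions + noise, truth=truth)


# ---------------------------------------------------------------------------
# partition comparison
# ---------------------------------------------------------------------------


def _as_labels(partition, n: int | None = None) -> np.ndarray:
    """Accept a label vector or an iterable of index sets; validate that
    it partitions 0..n-1."""
    if isinstance(partition, np.ndarray) or (
            partition and np.isscalar(next(iter(partition)))):
        labels = np.asarray(partition, dtype=np.int64)
        if n is not None and len(labels) != n:
            raise ValueError("partitions must cover the same point set")
        return labels
    blocks = [sorted(b) for b in partition]
    flat = [i for b in blocks for i in b]
    size = n if n is not None else (max(flat) + 1 if flat else 0)
    if sorted(flat) != list(range(size)):
        raise ValueError("input is not a partition of 0..n-1")
    labels = np.empty(size, dtype=np.int64)
    for lab, b in enumerate(blocks):
        labels[b] = lab
    return labels


def misclustered_points(result_partition, truth_partition) -> set[int]:
    """Points whose result cluster contains a point outside their truth
    cluster — equivalently, all members of impure result clusters."""
    result = _as_labels(result_partition)
    truth = _as_labels(truth_partition, n=len(result))
    out: set[int] = set()
    for lab in np.unique(result):
        members = np.flatnonzero(result == lab)
        if len(np.unique(truth[members])) > 1:
            out.update(int(i) for i in members)
    return out


def misclustering_rates(result, truth) -> dict:
    """Both directions of Eq.-style misclustering, as fractions of n."""
    result = _as_labels(result)
    truth = _as_labels(truth, n=len(result))
    n = len(result)
    return {
        "by_reference": len(misclustered_points(result, truth)) / n,
        "by_result": len(misclustered_points(truth, result)) / n,
    }


# ---------------------------------------------------------------------------
# the sigma x lambda sweep
# ---------------------------------------------------------------------------


def run_sweep(sigmas=(0.1, 0.3, 0.5), lambda_multipliers=(1.0, 1.5, 2.0, 2.5, 3.0),
              replicates: int = 10, seed: int = 0,
              sim_config: SimConfig = SimConfig()) -> pd.DataFrame:
    """Cluster artificial data over a grid of noise levels and merge
    thresholds.

    The merge threshold for each cell is ``multiplier * sigma``;
    the elevation weight is 1 inside the simulation because the
    artificial grid is isotropic.  Returns one row per
    (sigma, multiplier, replicate) with both misclustering rates, the
    final cluster count and the wall-clock runtime.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for sigma in sigmas:
        for mult in lambda_multipliers:
            child_seeds = ss.spawn(1)[0].generate_state(replicates) % (2 ** 31)
            for rep in range(replicates):
                cfg = SimConfig(points_per_class=sim_config.points_per_class,
                                n_classes=sim_config.n_classes,
                                coord_max=sim_config.coord_max,
                                sigma=float(sigma),
                                rng_seed=int(child_seeds[rep]))
                data = generate_sim_data(cfg)
                pts = [RegPoint(position=p, class_id=int(c))
                       for p, c in zip(data.observations, data.classes)]
                t0 = time.perf_counter()
                z, clusters = register_blooms(
                    pts, RegistrationConfig(merge_threshold=float(mult * sigma),
                                            elevation_weight=1.0))
                runtime = time.perf_counter() - t0
                rates = misclustering_rates(z, data.truth)
                rows.append({
                    "sigma": float(sigma),
                    "lambda_multiplier": float(mult),
                    "replicate": rep,
                    "rate_by_reference": rates["by_reference"],
                    "rate_by_result": rates["by_result"],
                    "n_clusters": len(clusters),
                    "runtime_s": runtime,
                })
    return pd.DataFrame(rows)


def threshold_coverage(k: float) -> float:
    """Percent of the per-direction position error covered by a merge
    threshold of k sigma: 100 P(|X| <= k sigma), X ~ Normal(0, sigma^2)."""
    if k <= 0:
        raise ValueError("multiplier must be positive")
    return 100.0 * (2.0 * stats.norm.cdf(k) - 1.0)
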