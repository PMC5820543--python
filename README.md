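# bloomcount

Counting cotton blooms (newly opened white flowers) in overlapping
nadir UAV images. Daily bloom counts track flowering progress per
breeding plot — flowering time, peak flowering and seasonal totals are
selection and management signals — but manual counting does not scale
to fields. `bloomcount` implements an aerial counting pipeline for
multi-view RGB imagery plus a photogrammetric dense point cloud:

1. **Plot image extraction** — each plot's boundary quadrangle is
   projected into every raw image; an image covers the plot (fully or
   partly) when at least 2 of the 4 vertices land inside it.
2. **Bloom detection** — bright-object screening on the CIELAB L
   channel (threshold 0.75 on per-image-normalized L, objects < 15 px
   removed, objects closer than a 20 px flower diameter merged), then
   a 7-layer CNN classifies each 36×36 candidate patch as bloom /
   non-bloom.
3. **Projection** — each detection's pixel ray is cast into the dense
   point cloud; the bloom's 3D position is the cloud point nearest to
   the ray (detections with no cloud point within the hit radius
   cannot be counted).
4. **Registration** — the same bloom appears in several images, so
   detections are merged by constrained agglomerative clustering.
   Two detections from the *same* image can never be the same bloom
   (a cannot-link constraint): the inter-cluster distance is

   d(μᵢ, μⱼ) = √((Δx)² + (Δy)² + w²(Δz)²)  if Eᵢ ∩ Eⱼ = ∅,  +∞ otherwise

   where Eᵢ is the set of source images in cluster *i* and w = 0.5
   down-weights the elevation axis (the least accurate axis of a
   multi-view-stereo reconstruction). Clusters are merged greedily,
   in index order, whenever the distance falls strictly below a
   threshold λ.
5. **Quality gating** — each plot's cloud is rasterized into a 1.3 cm
   elevation grid, a ground plane is fitted by MLESAC, cells are split
   into ground/canopy at 0.1 m above the plane, and the point cloud
   coverage PCC = canopy / (canopy + empty) is computed. Plots with
   PCC < 0.8 are excluded; with coverage *p*, missed blooms out of *n*
   follow Binomial(n, 1 − p).

No field imagery ships with the package: the `synthfield` module
generates a complete synthetic campaign (plots, canopy point cloud
with controllable completeness, blooms, camera poses, rendered nadir
images at ~3.2 mm ground pixel size, known truth), and the
`simulation` module reproduces the artificial-data study of the
registration algorithm (10 image classes × 125 distinct integer-grid
points, Gaussian position noise of RMS magnitude σ, thresholds
λ = 1…3 σ).

## Worked example

Cluster one artificial dataset at noise σ = 0.1 with threshold λ = 2σ:

```python
import numpy as np
from bloomcount.simulation import SimConfig, generate_sim_data, misclustering_rates
from bloomcount.registration import RegPoint, RegistrationConfig, register_blooms

cfg = SimConfig(sigma=0.1, rng_seed=42)
data = generate_sim_data(cfg)
points = [RegPoint(p, int(c)) for p, c in zip(data.observations, data.classes)]
z, clusters = register_blooms(
    points, RegistrationConfig(merge_threshold=2 * cfg.sigma, elevation_weight=1.0))
rates = misclustering_rates(z, data.truth)
print(f"points: {len(points)}   true blooms: {len(np.unique(data.truth))}")
print(f"registered clusters: {len(clusters)}")
print(f"misclustering by reference: {rates['by_reference']:.4f}")
print(f"misclustering by result:    {rates['by_result']:.4f}")
```

prints

```
points: 1250   true blooms: 729
registered clusters: 771
misclustering by reference: 0.0000
misclustering by result:    0.0720
```

1,250 noisy observations of 729 distinct blooms collapse to 771
clusters. At this low noise no two distinct blooms are wrongly merged
(`by reference` = 0 — every result cluster is pure), while 7% of the
points sit in blooms that were split across clusters (`by result`),
i.e. the algorithm errs toward counting a bloom twice rather than
merging two blooms, and a larger λ trades the one error for the other.

The same stages run from the shell — `bloomcount synth` writes a
synthetic field (PLY cloud, camera JSON, plot CSV, rendered PNGs),
and `bloomcount run --config cfg.yaml --out counts.csv` executes the
whole pipeline; see `bloomcount --help` for the per-stage subcommands
(`extract`, `screen`, `train`, `classify`, `register`, `quality`,
`simulate`).

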