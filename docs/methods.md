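# Methods

This note documents the models implemented in `bloomcount`, the
parameter defaults and why they were chosen, the numerical details a
user may need to reproduce or modify a run, and what the synthetic
fixtures do and do not establish about real field data.

## Coordinate conventions

Pixels are 0-based `(row, col)` with the origin at the image's top
left. The world frame is a local metric frame `(easting, northing,
elevation)` in meters; no geodetic transforms are performed, and
fixtures generate coordinates directly in this frame. Projection
uses an ideal pinhole camera: `p_cam = R (p − C)`, `col = c_col +
(f/pitch)·x/z`, `row = c_row + (f/pitch)·y/z` for depth `z > 0`. No
lens-distortion model is applied; if one were needed it would plug in
between the normalized camera coordinates and the pixel mapping. The
ground pixel size of a nadir camera is `pitch · H / f` (pitch and
focal length in mm, flight height H in m): an 18 mm lens at 15 m with
a 3.8 µm pitch gives ≈ 3.17 mm/px, the scale at which the screening
constants below are meaningful.

## Bright-object screening

Candidate patches come from the CIELAB lightness channel of each plot
image (D65, standard sRGB linearization): L is normalized by its own
maximum over the plot image — a per-image adaptive normalization that
absorbs global exposure differences — and thresholded at 0.75
(strict >). Connected components use 8-connectivity so diagonal
fragments of one flower stay together. Components under 15 px are
noise; components whose centroids are closer than 20 px (about one
flower diameter at 3.17 mm/px) are merged transitively via union-find
— centroid-to-centroid distance was chosen over nearest-boundary
distance because it is deterministic and cheap, and the two differ
only for elongated fragments. One 36×36 patch is cut per merged
object, centered on the pixel-area-weighted centroid of the union,
rounded to the nearest pixel; border patches are zero-padded to full
size and flagged. An all-black image yields no candidates rather than
a division error.

Candidate count is monotone non-increasing in the threshold and the
minimum object size on a fixed image, and screening is stateless
(idempotent).

## The patch classifier

The network is the classic seven-layer small-patch stack: input
36×36×3 → conv 5×5×20 → maxpool 2×2 → conv 5×5×50 → maxpool 2×2 →
fully connected 256 (ReLU) → fully connected 2 → softmax, 488,140
parameters at the defaults. Kernel and filter counts are
configurable; the layer *sequence* (2 conv, 2 pool, 2 FC) is fixed
and validated.

Training is plain mini-batch SGD (no momentum): 30 epochs, initial
learning rate 0.01 decreased ×0.1 every 10 epochs, batch 256, L2
weight decay 0.01 on weights (not biases), cross-entropy loss, He
initialization. The loss on this schedule plateaus around epoch 20,
so a snapshot of the weights is kept at a configurable early-snapshot
epoch (default 20) and can be swapped in after training. Everything
is float32 numpy (im2col convolutions); with a fixed seed a training
run is reproducible on one platform. Inputs are scaled to [0,1] and
centered at 0.5. The decision rule keeps candidates whose bloom
probability is *strictly* above 0.5.

`confusion_summary` reports over/underestimation as
`100·(predicted − actual)/actual` rounded to the nearest integer,
where `predicted` counts everything called a bloom and `actual` is
the actual-bloom row sum. Per-class ratio tables of this kind are
printed with ambiguous orientation in the literature, so the summary
names each ratio by its explicit numerator/denominator
(`correct_of_predicted_bloom`, `detected_of_actual_bloom`, …) instead
of asserting which one is "precision".

## Constrained registration

Detections are points `(x, y, z)` tagged with their source image (the
class). The weighted distance `√(Δx² + Δy² + w²Δz²)` with `w = 0.5`
halves the influence of elevation, the least accurate axis of
multi-view-stereo depth; inside the isotropic simulation grid `w = 1`.
Between clusters the distance is taken between centers when the
source-image sets are disjoint and is infinite otherwise — the
cannot-link constraint.

The merging loop is deliberately literal and deterministic:

* initialization: every point is its own cluster, cluster ids are the
  point indices and are never renumbered;
* a pass visits live clusters in ascending id; for cluster *i* the
  eligible set is every live cluster whose class set is disjoint from
  *i*'s **current** class set; *i* merges into the nearest eligible
  cluster iff the distance is strictly below λ, and the absorbed
  points take the target's id (the target survives);
* centers are recomputed (as member means) only at the end of a full
  pass, so merges within a pass measure distances against the
  previous pass's centers — class sets, by contrast, are always
  current. This is the straightforward reading of an
  update-at-pass-end loop; immediate center updates would be a
  one-line change and give a slightly different (still valid) greedy.
* distance ties break toward the lowest cluster id; the loop stops
  when a pass performs no merge. Each merging pass strictly decreases
  the cluster count, so at most n − 1 passes run.

Invariants checked in the test suite on every run: no final cluster
holds two detections from one image; the clusters partition the
points; at convergence every pair of constraint-compatible clusters
is at least λ apart (with final centers); with exact duplicate
positions and any λ below the minimal inter-position distance the
true grouping is recovered exactly. The implementation is vectorized
over the inner candidate scan; a pure-python literal replay of the
loop serves as its oracle on small instances.

Per-plot counting assigns each cluster center to the plot quadrangle
containing it in the easting–northing plane (boundary points count as
inside); a center on a shared edge goes to the first plot in file
order; overlapping plot polygons are an invalid layout and raise.
There is no field-data default for λ — it is user-set (the synthetic
pipeline default, 0.15 m, is twice the position-error scale of the
fixtures).

## Point-cloud quality

Each plot is rasterized into a 2D elevation grid (default cell 1.3
cm) over the quadrangle's bounding box; a cell exists iff its center
lies inside the quadrangle, holds the **maximum** elevation of its
points (the canopy top surface, which is what the height split
needs), and stays empty — never interpolated — when no point falls in
it.

The ground plane is fitted with MLESAC on the plot's non-empty cells:
random 3-point hypotheses, each scored by the negative log-likelihood
of a Gaussian-inlier (σ = 0.02 m) + uniform-outlier mixture of
point–plane distances, with the mixing weight re-estimated per
hypothesis by a 3-step EM fixed point; the uniform support is the
observed elevation span. The best hypothesis is refined by a total
least-squares (SVD) fit to its inliers (|d| ≤ 2.5σ). Defaults (500
iterations, σ = 0.02 m) suit centimetric ground roughness under a
0.5–1 m canopy; both are configurable, and the fit is deterministic
given its seed. Degenerate (collinear) samples are skipped; if every
sample is degenerate the fit raises.

Cells more than 0.1 m (strict >) above the plane are canopy, others
ground. Point cloud coverage is `PCC = canopy / (canopy + empty)`:
empty cells count against coverage because holes inside a planted
plot are almost always unreconstructed canopy. An unvegetated plot
(no canopy, no empties) gets PCC 0 by convention. Plots with
PCC < 0.8 (strict <) are excluded from counting. Under coverage *p*,
the number of blooms without a valid cloud point out of *n* is
Binomial(n, 1 − p): mean miss `n(1 − p)`, relative error `1 − p`.

## The artificial-data study

Each dataset: 10 classes ("images") × 125 **distinct** integer
triples drawn uniformly from {0,…,9}³ by rejection; points sharing
coordinates across classes are the same true bloom. Per-axis Gaussian
noise with standard deviation σ/√3 is added, so the 3D error
magnitude has RMS σ. This is the one reading of "position error of
magnitude σ" that is geometrically coherent — an error *magnitude*
cannot itself be normally distributed — and it is implemented as the
root-mean-square of the vector error; the Monte-Carlo moment check in
the tests verifies it to 2%.

A misclustered point (with respect to a reference partition) is one
whose cluster contains a point the reference places elsewhere —
equivalently, every member of an impure cluster. Both directions are
reported: `by_reference` scores the clustering against the truth and
fires when distinct true blooms are merged (over-clustering);
`by_result` swaps the roles and fires when one true bloom is split
(under-clustering). Beware that result-section narratives in the
literature sometimes attach these two labels the other way around;
the definitions here are the operational ones above, and the sweep
trends in the test suite are asserted on the quantity each trend is
actually about (the over-merge direction is near zero at σ = 0.1 for
every λ; the final cluster count is non-increasing in λ at fixed σ).

The sweep crosses σ ∈ {0.1,…,0.5}, λ ∈ {1, 1.5, 2, 2.5, 3}·σ (these
multipliers cover 68–99.7% of a per-direction Gaussian error) with 10
replicates by default; runtimes are logged but never asserted, being
hardware-dependent.

## The synthetic field

`synthfield` emulates the campaign the pipeline was designed for: a
12×11 grid of single-plant plots at 1.5 m spacing (1.2 m plot
squares), hemispherical canopy domes (radius 0.45 m, apex 0.8 m, 2 cm
surface noise) over flat ground, blooms as 3 cm-radius near-white
disks sitting on the dome, and a nadir camera grid at 15 m with the
real imaging scale (≈3.17 mm/px) and enough overlap that every plot
appears in at least three views.

Sampling is a jittered lattice at **half** the raster cell size
inside plots (jitter < a quarter pitch), which guarantees by
construction that a complete plot rasterizes with zero empty cells;
alleys are sampled at the cell size (they only matter for
rendering). Rendering is far-to-near point splatting with a splat
just large enough to close inter-sample gaps — no mesh, no ray-traced
occlusion (nearer geometry still hides farther geometry through the
depth ordering).

Incompleteness: dropout removes contiguous patches (default radius
0.12 m, a realistic canopy-sized reconstruction hole) of a plot's
canopy samples until the requested fraction is gone, trimming the
last patch from its rim so the realized per-plot removal matches the
target; the measured PCC then tracks `1 − dropout` to within a few
percent (patch-edge cells keep a sample, so cell-level coverage runs
slightly above the sample-level target). Dropout applies to the
*delivered* cloud only — rendered images always use the full scene,
because photographs show every bloom and incompleteness is a
reconstruction artifact. A bloom over a hole is therefore detected in
the images but finds no cloud point within the 0.05 m hit radius, is
flagged unprojectable, and goes uncounted — exactly the binomial miss
mechanism of the quality model.

The default scene is diffuse-light: no specular highlights, the
condition under which bright-object screening is cleanest.
Distractor glints can be enabled (`glints_per_plot`) to stress the
classifier, and the training-patch generator always includes the
classifier's confusion cases (specular-highlight-like blobs,
boll-like creamy blobs, bare ground) in its non-bloom class, with
equal class counts available for balanced training.

What the fixtures do **not** model: real canopy texture and leaf
geometry, shadows and non-uniform illumination, pink day-old flowers,
wind-driven scene motion, reconstruction noise beyond hole-punching,
and oblique views. Passing the end-to-end tests therefore shows the
pipeline's machinery is correct and internally consistent at the real
imaging scale — not that the classifier or the thresholds transfer to
arbitrary field imagery.

## Problem sizes in the test suite

The end-to-end tests run 3×3-plot fields (every per-stage constant at
its full-scale default), the classifier fixtures train on 1,200
balanced patches for 3 epochs (accuracy saturates within the first
epoch on the synthetic task), the registration property suite uses 50
reduced artificial datasets (8 classes × 30 points) plus the default
1,250-point scale where the dataset size itself is the claim, and the
sweep runs 3 σ-values × 5 thresholds × 3 replicates. These sizes are
the package's own test-budget choices; all module defaults remain the
full-scale values described above.

## Known limitations

* The ray–cloud intersection takes the global perpendicular-distance
  minimum among points in front of the camera; it does not reason
  about visibility order, so a ray that passes close to foreground
  geometry before reaching its target can bind to the wrong surface.
* Plot crops of one raw image can overlap; duplicate detections of
  one blob through two crops are collapsed per image by a
  20 px-radius deduplication before registration.
* MLESAC assumes the ground is locally planar per plot and visible in
  enough cells; a plot fully carpeted by canopy gives an
  unconstrained ground fit.
* The CNN is trained on synthetic patches unless a model file is
  supplied; for real imagery it must be retrained on labeled
  candidates from the target campaign.
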