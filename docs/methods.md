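# Methods

This note documents the models, conventions and design choices behind
berrypheno, in the spirit of a package reference manual.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate and raster conventions

All coordinates are 0-based image coordinates, x rightward and y downward,
matching common annotation tools.  A pixel at row r, column c occupies the
unit square [c, c+1) × [r, r+1); its center is (c+0.5, r+0.5).

**Rasterization** uses the pixel-center rule: a pixel belongs to a polygon
iff its center is inside.  Centers exactly on the boundary are resolved
half-open (top/left inclusive) by sampling the center nudged by +1e-9 in both
axes.  This makes areas reproducible — the axis-aligned square with corners
(10,10)–(20,20) rasterizes to exactly 100 pixels.  The point-in-polygon test
is `matplotlib.path.Path.contains_points`; the test suite cross-checks it
against per-pixel shapely queries.

**Minimum rotated rectangle.**  The enclosing rectangle of minimum area over
all orientations is flush with a convex-hull edge (rotating-calipers
property), so the search reduces to hull edges; the implementation delegates
to `shapely.minimum_rotated_rectangle` after a `scipy.spatial.ConvexHull`
reduction, and tests verify it against a brute-force 0.01°-step orientation
sweep (max relative deviation on random point sets ≤ 0.1%) and rotation
invariance to 1e-6 relative.  For masks, the rectangle encloses the *corner
points of member pixels*, not their centers, so the box geometrically
contains every pixel square; consequently A ≤ A_b holds exactly and a filled
rectangle mask attains compactness exactly 1.  The canonical form stores
width ≥ height and the orientation angle modulo 90° in [0, 90); a rectangle's
side directions are only defined up to a quarter turn once side roles are
unpinned, so this is the tightest canonicalization that always exists.  The
four corner points are kept alongside for exact reconstruction.

**Erosion** uses a Euclidean-disk structuring element of the given radius.
If erosion would empty a mask entirely, the original mask is returned with a
`not eroded` flag so that very small berries still receive a color decision.

## Traits

* **Count** N_b is the number of detected visible instances; no amodal
  completion is attempted.
* **Maturity** is N_m / N_b from per-instance labels, undefined (an error,
  not 0) for an empty view.
* **Compactness** is A / A_b with A the *union* area of all berry masks.
  Union rather than sum: predicted masks of touching berries overlap, and
  the overlapped pixels would otherwise be double-counted.
* Branch-level traits are unweighted means over views, as multiple views of
  the same branch are interchangeable samples of it.

### Hue-based maturity

Ripe blueberries are blue/purple, unripe ones green through red; the Hue
channel separates them while discounting illumination differences, which
matters for outdoor imagery.  Hue is computed on the 0–180 half-degree scale
(the convention under which the mature thresholds 0/30/150/180 are stated).
The decision is per berry: erode the mask boundary by 10 px (default) to
strip background pixels bleeding across the outline, then call the berry
mature iff *more than half* of the remaining pixels have Hue strictly inside
(0, 30) ∪ (150, 180).  The majority rule is this package's choice of
aggregation from the per-pixel rule to a per-berry label; boundary Hue values
(exactly 0, 30, 150 or 180) count as immature because the inequalities are
strict.

## Evaluation

Matching is greedy in descending score order (ties: larger best IOU, then
input order); each prediction claims the unmatched ground truth of its class
with the highest IOU if that IOU reaches the threshold.  This gives the
standard bookkeeping identities TP+FN = #GT and TP+FP = #predictions at
every threshold.

AP uses the monotonized all-point interpolation: precision at each point is
replaced by the maximum precision at equal-or-higher recall, and AP is the
area under the resulting step curve.  mAP averages per-class APs over the
classes present in the ground truth (absent classes are excluded with a
warning); per-class averaging was chosen so that failures on the rarer class
are not hidden by the dominant one.  mIOU averages the IOU of matched pairs
only — it isolates mask shape accuracy from detection accuracy.

### Error taxonomy

After class-agnostic matching at a primary threshold (default 0.5), the
remaining instances are assigned, in priority order and each at most once:

1. **one-as-two** — an unmatched ground truth overlapped (IOU ≥ floor,
   default 0.1) by ≥ 2 unmatched predictions whose *union* reaches the
   primary threshold against it;
2. **two-as-one** — an unmatched prediction overlapping ≥ 2 remaining ground
   truths at ≥ floor each;
3. **partial** — a remaining ground truth with exactly one remaining
   prediction overlapping it at an IOU in [floor, primary);
4. **missed** — a remaining ground truth with no remaining prediction
   overlap ≥ floor.

All four rules consider only unmatched, not-yet-consumed instances; matched
instances count as consumed by the matching itself.  That is the only
consistent reading of "each error event assigned exactly one type".  The
floor threshold is a package-defined constant (the taxonomy itself is
qualitative); events that fit no rule (e.g. two sub-floor fragments) are
left untallied rather than forced into a category.

## Count calibration

`CountCalibrator` fits truth ~ detected by OLS (`scipy.stats.linregress`
underneath) and reports intercept, slope, their standard errors, in-sample
R² and RMSE.  The regression direction maps the detected count to the true
count, i.e. the direction in which the correction is applied.  Constant
truth is a 0/0 in R² and is defined as 0 (zero explained variance) rather
than rejected.  No train/test split is used; the correction is descriptive,
in keeping with how such calibrations are reported.

## Synthetic scenes

The generator's purpose is to exercise the geometry, color and evaluation
logic with exact ground truth, not to imitate photographs.

* Berries are disks with radius ~ N(13, 2²) px on a 320×320 frame — roughly
  the berry-to-frame proportion of a cropped branch photo.  Defaults: 5–25
  berries per branch in 1–4 clusters (cluster counts of real branches run
  about 2–4), maturity probability 0.55 (mid-season, roughly half blue).
* Colors are drawn per class in disjoint Hue ranges — mature (4, 28) ∪
  (152, 176), immature (38, 98) — leaving a few units of margin inside the
  classifier's thresholds so that 8-bit quantization cannot cross them;
  saturation and value are uniform in (0.55, 0.95) and (0.35, 0.85).  The
  background is a flat brown, standing in for an artificial backdrop.
  Optional Gaussian color noise degrades the separation.
* Occlusion comes from z-ordering: each berry's visible mask is its disk
  minus the union of disks in front.  A berry occluded into two pieces
  remains one instance with a disconnected visible mask; a fully hidden
  berry stays in the ground truth flagged invisible.  `overlap_intensity`
  in [0, 1) shrinks within-cluster spacing; at exactly 0 placement is
  rejection-sampled to keep disks disjoint, so every berry is fully visible.
* A *branch sample* draws berry count, radii, labels, colors and cluster
  count once and re-draws placement and z-order per view.  Views are
  independent re-projections, not true 3-D rotations — sufficient to
  exercise multi-view aggregation, not to model view-to-view correlation of
  occlusion.
* Everything is reproducible bit-exactly from (parameters, seed).

### Detector-like perturbations

`perturb_to_detections` degrades ground truth per instance with given
probabilities: **drop** (→ missed), **split** (→ one-as-two; the mask is cut
at its median member column with a 3-px seam discarded, so each fragment
holds strictly less than half the pixels and cannot itself match the berry),
**merge** (→ two-as-one; union with the nearest unprocessed neighbour,
dilated by ~0.3× the pair's mean radius — a merged detection is one sloppy
blob, and the dilation keeps its IOU with either single berry below the
matching threshold), **jitter** (→ partial; the mask is translated by
`jitter_px`, capped at ~1.1× the berry radius so the displaced detection
still overlaps its berry above the taxonomy floor), and **relabel** (class
flip).  Unperturbed instances get scores in [0.85, 1), perturbed ones in
[0.4, 0.8).

### What passing on synthetic data does and does not show

The synthetic scenes have hard color boundaries, no leaves, stems, shadows,
specular highlights or blur, and circular berries.  Tests passing on them
demonstrate that the geometry, metric and calibration code is correct and
internally consistent — not that any particular segmentation network
generalizes to field imagery, nor that the Hue thresholds are optimal for a
given camera.

## Problem sizes and numerical choices

The study-scale runs in the tests and the acceptance script use 104 branch
samples × 5 views (520 images) at 320×320 px — the full sampling design at a
reduced image resolution, which preserves every counting and aggregation
property while keeping mask areas in the tens of thousands of pixels.
Rasterized-geometry comparisons use tolerances reflecting pixelation (3% for
eroded disk areas at radius 20, 0.01 absolute for disk compactness at
radius 100); exact identities (counts, union areas, full-rectangle
compactness, bookkeeping) are asserted exactly.  Ties in matching are broken
deterministically (score, then best IOU, then input order), so all metrics
are invariant to prediction input order with distinct scores.

## Known limitations

* Compactness is defined on the whole branch; per-cluster (sub-branch)
  compactness and pedicel-length effects are out of scope.
* The polygon export of a disconnected visible mask traces only its largest
  piece; raster masks remain the authoritative representation internally.
* mIOU is computed over matched pairs only; with very few matches it says
  little about overall mask quality.
* The VIA reader handles polygon regions with a configurable maturity
  attribute (default key `"maturity"`); other shape types are skipped with
  warnings rather than converted.
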