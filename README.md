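# berrypheno

Image-based phenotyping of blueberry fruit clusters from per-berry instance
segmentations.

Blueberry breeders and growers select genotypes and schedule (mechanical)
harvests using three branch-level traits: how many berries a branch carries,
what fraction of them are ripe, and how tightly the fruit is clustered.
Modern instance-segmentation networks can outline every berry in a field
photo; this package implements everything around such a segmenter — it
consumes per-berry masks from *any* source and turns them into traits,
evaluates segmentation quality, and calibrates counts against manual ground
truth.  A synthetic cluster generator with exact ground truth makes the whole
pipeline testable without field images or a trained network.

## Traits

For one view of a branch with detected berry instances:

* **count** — N_b, the number of detected berries;
* **maturity** — N_m / N_b, the fraction of detected berries labelled mature
  (blue), with an optional *objective* per-berry call from color alone: a
  berry is mature when the majority of its mask pixels (after a 10-px
  boundary erosion that strips background bleed) have a Hue h on the 0–180
  half-degree scale with 0 < h < 30 or 150 < h < 180;
* **compactness** — A / A_b, where A is the union area of all berry masks and
  A_b the area of the *minimum-area rotated rectangle* enclosing them.  Using
  the rotated rather than axis-aligned box makes the value invariant to the
  branch's orientation in the image.

Branch-level traits are the unweighted means over the (typically five) views
covering the branch.  Because hidden berries cannot be detected in a 2-D
view, detected counts undercount the branch; an OLS line N_t ≈ a + b·N_b
(fitted pooled and per cultivar, with R² and RMSE) calibrates them.

## Evaluation

Predictions are scored against ground truth with the standard COCO-style
protocol: greedy score-ordered matching on mask IOU, per-class average
precision (area under the monotonized precision–recall curve) over IOU
thresholds 0.5–0.95 in steps of 0.05, class-averaged mAP, and mean IOU over
matched pairs (mask accuracy).  A qualitative tally classifies residual
errors into four modes: one berry detected as two, missed detection, two
berries detected as one, and partial detection.

## Worked example

```python
import numpy as np
from berrypheno import SceneParams, generate_branch_sample, fit_linear
from berrypheno.traits import aggregate_sample, traits_frame

params = SceneParams(overlap_intensity=0.4)
rng = np.random.default_rng(0)
samples, detected, truth = [], [], []
for s in range(8):
    branch = generate_branch_sample(params, n_views=5, rng=rng, sample_id=f"branch{s}")
    records = [scene.trait_record() for scene in branch.scenes]
    agg = aggregate_sample(branch.sample_id, branch.cultivar, records,
                           n_true=branch.n_total, n_clusters=branch.n_clusters)
    samples.append(agg)
    detected.append(agg.berry_count)
    truth.append(branch.n_total)

df = traits_frame(samples)
print(df[df["view"] == "mean"][["sample_id", "N_b", "maturity", "compactness"]]
      .round(3).to_string(index=False))
fit = fit_linear(detected, truth)
print(f"calibration: N_t = {fit.intercept:.3f} + {fit.slope:.3f} * N_b  "
      f"(R^2 = {fit.r2:.3f}, RMSE = {fit.rmse:.3f}, n = {fit.n})")
```

prints

```
sample_id  N_b  maturity  compactness
  branch0 21.2     0.442        0.240
  branch1 18.4     0.432        0.670
  ...
  branch7 13.8     0.565        0.646
calibration: N_t = -2.339 + 1.216 * N_b  (R^2 = 0.644, RMSE = 1.783, n = 8)
```

Each row is one branch: `N_b` is the mean detected berry count over its five
views, `maturity` the mean mature fraction, `compactness` the mean mask-to-box
area ratio.  The fitted slope above 1 with a negative intercept is the
occlusion correction: the more berries a branch carries, the more of them are
hidden in any single view, so the true count grows faster than the detected
one.

The same pipeline is available from a shell:

```sh
berrypheno simulate --out data --samples 8 --seed 0
berrypheno extract  --detections data/detections.json --images data/images \
                    --ground-truth data/ground_truth.csv --out traits.csv
berrypheno evaluate --predictions data/detections.json \
                    --ground-truth data/ground_truth_detections.json \
                    --images data/images --out report.json --plot pr.png
berrypheno calibrate --traits traits.csv --out calibration.csv
```

## Layout

| module | contents |
| --- | --- |
| `berrypheno.geometry` | rasterization, mask IOU, union area, minimum rotated rectangle, disk erosion |
| `berrypheno.annotation_io` | VIA 2.x project JSON, detection JSON, ground-truth CSV, correction diff |
| `berrypheno.traits` | per-view traits, Hue maturity classifier, per-branch aggregation |
| `berrypheno.evaluation` | matching, AP/mAP, mean IOU, error taxonomy, report + PR plots |
| `berrypheno.calibration` | `CountCalibrator` estimator, pooled/per-cultivar fits |
| `berrypheno.synthetic` | scene/branch generators, detector-like perturbations |
| `berrypheno.cli` / `berrypheno.pipeline` | `berrypheno` console script and its file-based steps |

See `docs/methods.md` for the model assumptions, parameter choices, and
limitations.
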