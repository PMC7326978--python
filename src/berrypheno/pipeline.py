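"""File-based pipeline steps tying the modules together.

These functions do the actual work of the command-line interface: write a
synthetic dataset to disk in the package's interchange formats, extract traits
from detection JSON plus images, evaluate predictions against ground truth,
and fit the count calibration.  They operate purely on paths and DataFrames so
they can be driven from the CLI or called directly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import annotation_io as aio
from . import calibration as cal
from . import evaluation as ev
from . import traits as tr
from .synthetic import DetectionNoise, SceneParams, generate_branch_sample, perturb_to_detections

__all__ = [
    "simulate_dataset",
    "extract_traits",
    "evaluate_detections",
    "calibrate_counts",
]

DEFAULT_CULTIVARS = ("Emerald", "Farthing", "Meadowlark", "Star")


def simulate_dataset(
    out_dir: str | Path,
    n_samples: int = 8,
    n_views: int = 5,
    seed: int = 0,
    params: SceneParams | None = None,
    noise: DetectionNoise | None = None,
    cultivars: Sequence[str] = DEFAULT_CULTIVARS,
) -> dict:
    """Write a complete synthetic dataset: images, annotations, detections, truth CSV.

    Samples are assigned to cultivars round-robin.  Ground truth goes out both
    as a VIA project (full berry outlines, annotation-style) and as detection
    JSON (visible-mask polygons, scoreless); predictions are the perturbed
    detections.  Returns a manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    params = params or SceneParams()
    noise = noise or DetectionNoise()
    rng = np.random.default_rng(seed)

    regions: list[aio.AnnotatedRegion] = []
    gt_instances: list[aio.DetectionInstance] = []
    pred_instances: list[aio.DetectionInstance] = []
    truth_rows = []
    for s in range(n_samples):
        cultivar = cultivars[s % len(cultivars)]
        sample_id = f"{cultivar}_{s:03d}"
        sample = generate_branch_sample(
            params, n_views=n_views, rng=rng, sample_id=sample_id, cultivar=cultivar
        )
        for v, scene in enumerate(sample.scenes):
            image_name = f"{scene.image_id}.png"
            scene.image_id = image_name
            iio.imwrite(out / "images" / image_name, scene.image)
            for berry in scene.berries:
                if berry.visible:
                    regions.append(
                        aio.AnnotatedRegion(image_name, berry.outline, berry.label)
                    )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # sliver masks may trace tiny contours
                gt_instances.extend(
                    aio.DetectionInstance(
                        image_id=image_name,
                        label=inst.label,
                        polygon=aio.polygon_from_mask(inst.mask),
                    )
                    for inst in scene.ground_truth_instances()
                )
                pred_instances.extend(
                    aio.DetectionInstance(
                        image_id=image_name,
                        label=det.label,
                        score=det.score,
                        polygon=aio.polygon_from_mask(det.mask),
                    )
                    for det in perturb_to_detections(scene, noise, rng=rng)
                )
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "cultivar": cultivar,
                    "view": v,
                    "image": image_name,
                    "N_t": sample.n_total,
                    "N_c": sample.n_clusters,
                }
            )

    (out / "annotations.json").write_text(aio.write_via(regions))
    (out / "ground_truth_detections.json").write_text(aio.write_detections(gt_instances))
    (out / "detections.json").write_text(aio.write_detections(pred_instances))
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    manifest = {
        "n_samples": n_samples,
        "n_views": n_views,
        "seed": seed,
        "image_size": list(params.image_size),
        "overlap_intensity": params.overlap_intensity,
        "noise": {
            "drop": noise.drop,
            "split": noise.split,
            "merge": noise.merge,
            "jitter": noise.jitter,
            "relabel": noise.relabel,
            "jitter_px": noise.jitter_px,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _load_frames(image_dir: str | Path, image_ids: Sequence[str]) -> dict[str, np.ndarray]:
    images = {}
    missing = []
    for image_id in dict.fromkeys(image_ids):
        path = Path(image_dir) / image_id
        if not path.exists():
            missing.append(image_id)
            continue
        images[image_id] = np.asarray(iio.imread(path))
    if missing:
        raise FileNotFoundError(f"images not found under {image_dir}: {missing[:5]}...")
    return images


def extract_traits(
    detections_path: str | Path,
    images_dir: str | Path,
    ground_truth_csv: str | Path | None = None,
    use_hue: bool = False,
    erosion_radius: float = tr.DEFAULT_EROSION_RADIUS,
) -> pd.DataFrame:
    """Per-view and per-sample trait table from detection JSON plus images.

    With ``use_hue`` the per-berry maturity comes from the objective Hue rule
    instead of the detection labels.  Images are grouped into samples via the
    ground-truth CSV when given; otherwise each image is its own sample.
    """
    instances = aio.read_detections(Path(detections_path).read_text())
    if not instances:
        raise ValueError(f"no detection records in {detections_path}")
    by_image = {}
    for inst in instances:
        by_image.setdefault(inst.image_id, []).append(inst)
    images = _load_frames(images_dir, list(by_image))

    if ground_truth_csv is not None:
        truth = aio.read_ground_truth(ground_truth_csv)
        groups = truth.groupby("sample_id", sort=True)
    else:
        truth = None

    def _record(image_id: str) -> tr.TraitRecord:
        image = images[image_id]
        view = by_image[image_id]
        if use_hue:

            def _hue_label(inst: aio.DetectionInstance) -> str:
                # slivers can rasterize to nothing; keep the given label then
                if inst.raster(image.shape[:2]).area == 0:
                    return inst.label
                return tr.hue_maturity(image, inst, erosion_radius)

            view = [
                aio.DetectionInstance(
                    image_id=inst.image_id,
                    label=_hue_label(inst),
                    score=inst.score,
                    polygon=inst.polygon,
                    mask=inst.mask,
                )
                for inst in view
            ]
        return tr.compute_traits(view, image.shape[:2])

    samples: list[tr.SampleTraits] = []
    if truth is not None:
        for sample_id, rows in groups:
            rows = rows.sort_values("view")
            records = [_record(img) for img in rows["image"] if img in by_image]
            if not records:
                warnings.warn(f"sample {sample_id!r} has no detected views; skipped")
                continue
            samples.append(
                tr.aggregate_sample(
                    str(sample_id),
                    str(rows["cultivar"].iloc[0]),
                    records,
                    n_true=int(rows["N_t"].iloc[0]),
                    n_clusters=int(rows["N_c"].iloc[0]),
                )
            )
    else:
        for image_id in sorted(by_image):
            samples.append(
                tr.aggregate_sample(image_id, "unknown", [_record(image_id)])
            )
    frame = tr.traits_frame(samples)
    if truth is not None:
        n_t = {s.sample_id: s.n_true for s in samples}
        n_c = {s.sample_id: s.n_clusters for s in samples}
        frame["N_t"] = frame["sample_id"].map(n_t)
        frame["N_c"] = frame["sample_id"].map(n_c)
    return frame


def _instances_from_ground_truth(text: str) -> list[aio.DetectionInstance]:
    """Accept ground truth as either a VIA project or detection JSON."""
    try:
        regions = aio.read_via(text)
        return [
            aio.DetectionInstance(image_id=r.image_id, label=r.label, polygon=r.outline)
            for r in regions
        ]
    except ValueError:
        return aio.read_detections(text)


def evaluate_detections(
    predictions_path: str | Path,
    ground_truth_path: str | Path,
    images_dir: str | Path,
    thresholds: Sequence[float] = ev.DEFAULT_IOU_THRESHOLDS,
    primary_threshold: float = 0.5,
    floor_threshold: float = 0.1,
) -> dict:
    """Evaluation report for a prediction file against a ground-truth file."""
    preds = aio.read_detections(Path(predictions_path).read_text())
    gts = _instances_from_ground_truth(Path(ground_truth_path).read_text())
    if not gts:
        raise ValueError(f"no ground-truth instances in {ground_truth_path}")
    gt_images = {g.image_id for g in gts}
    stray = sorted({p.image_id for p in preds} - gt_images)
    if stray:
        raise ValueError(f"prediction images absent from ground truth: {stray[:5]}")
    images = _load_frames(images_dir, sorted(gt_images))
    frames = {k: v.shape[:2] for k, v in images.items()}
    report = ev.evaluate_dataset(
        preds, gts, frames, thresholds, primary_threshold, floor_threshold
    )
    return report


def calibrate_counts(
    traits_csv: str | Path,
    ground_truth_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Pooled and per-cultivar count calibration from a traits table.

    Uses the per-sample mean rows.  ``N_t`` can come from the traits table
    itself (as written by :func:`extract_traits`) or be joined from a
    ground-truth CSV.
    """
    df = pd.read_csv(traits_csv)
    means = df[df["view"] == "mean"].copy()
    if "N_t" not in means.columns or means["N_t"].isna().any():
        if ground_truth_csv is None:
            raise ValueError("traits table lacks N_t; provide the ground-truth CSV")
        truth = aio.read_ground_truth(ground_truth_csv)
        per_sample = truth.groupby("sample_id")["N_t"].first()
        means["N_t"] = means["sample_id"].map(per_sample)
    if means["N_t"].isna().any():
        raise ValueError("some samples have no ground-truth count")
    return cal.calibrate_groups(means, detected_col="N_b", truth_col="N_t")
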