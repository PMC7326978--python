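"""Detection/segmentation evaluation: matching, AP/mAP, mean IOU, error taxonomy.

The conventions follow the common COCO-style instance evaluation: predictions
are processed in descending score order and greedily matched to the unmatched
ground truth of the same class with the highest mask IOU at or above the
threshold; AP is the area under the monotonized (all-point interpolated)
precision-recall curve; mAP averages per-class APs so that the rarer class is
not hidden by the dominant one; mIOU averages the IOU of the matched
(true-positive) pairs only, i.e. it measures mask shape accuracy separately
from detection accuracy.

A qualitative error taxonomy complements the scalar metrics with four failure
modes of berry detectors: one berry detected as two fragments, a missed berry,
two berries merged into one detection, and a partial detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotation_io import LABELS, DetectionInstance

__all__ = [
    "DEFAULT_IOU_THRESHOLDS",
    "MatchResult",
    "APResult",
    "ErrorTally",
    "iou_matrix",
    "match_instances",
    "average_precision",
    "mean_average_precision",
    "mean_iou",
    "classify_errors",
    "evaluate_dataset",
    "plot_pr_curves",
]

#: the standard IOU threshold grid, 0.5 to 0.95 in steps of 0.05
DEFAULT_IOU_THRESHOLDS: tuple[float, ...] = tuple(
    np.round(np.arange(0.5, 0.951, 0.05), 2)
)


@dataclass
class MatchResult:
    """Greedy prediction-to-ground-truth pairing at one IOU threshold."""

    iou_threshold: float
    pairs: list[tuple[int, int, float]]  # (pred index, gt index, IOU)
    unmatched_preds: list[int]
    unmatched_gts: list[int]

    @property
    def n_tp(self) -> int:
        return len(self.pairs)

    @property
    def n_fp(self) -> int:
        return len(self.unmatched_preds)

    @property
    def n_fn(self) -> int:
        return len(self.unmatched_gts)


@dataclass
class APResult:
    """Precision-recall curve and average precision for one class / threshold."""

    label: str
    iou_threshold: float
    recall: np.ndarray
    precision: np.ndarray
    ap: float


@dataclass
class ErrorTally:
    """Counts of the four qualitative detection error types."""

    one_as_two: int = 0
    missed: int = 0
    two_as_one: int = 0
    partial: int = 0

    def __add__(self, other: "ErrorTally") -> "ErrorTally":
        return ErrorTally(
            self.one_as_two + other.one_as_two,
            self.missed + other.missed,
            self.two_as_one + other.two_as_one,
            self.partial + other.partial,
        )

    @property
    def total(self) -> int:
        return self.one_as_two + self.missed + self.two_as_one + self.partial

    def as_dict(self) -> dict[str, int]:
        return {
            "one_as_two": self.one_as_two,
            "missed": self.missed,
            "two_as_one": self.two_as_one,
            "partial": self.partial,
        }


def iou_matrix(
    preds: Sequence[DetectionInstance],
    gts: Sequence[DetectionInstance],
    frame: tuple[int, int],
) -> np.ndarray:
    """Pairwise mask IOU matrix, shape (n_preds, n_gts)."""
    pm = [p.raster(frame).pixels for p in preds]
    gm = [g.raster(frame).pixels for g in gts]
    out = np.zeros((len(pm), len(gm)))
    for i, a in enumerate(pm):
        a_sum = int(a.sum())
        for j, b in enumerate(gm):
            inter = int(np.logical_and(a, b).sum())
            union = a_sum + int(b.sum()) - inter
            out[i, j] = inter / union if union > 0 else 0.0
    return out


def _pred_order(preds: Sequence[DetectionInstance], iou: np.ndarray) -> list[int]:
    # descending score; ties broken by larger best IOU, then stable input order
    best = iou.max(axis=1) if iou.size else np.zeros(len(preds))
    scores = np.array([p.score for p in preds], dtype=float)
    return list(np.lexsort((np.arange(len(preds)), -best, -scores)))


def match_instances(
    preds: Sequence[DetectionInstance],
    gts: Sequence[DetectionInstance],
    iou_threshold: float,
    frame: tuple[int, int],
    class_aware: bool = True,
    iou: np.ndarray | None = None,
) -> MatchResult:
    """Greedy score-ordered matching of predictions to ground truth.

    Each prediction claims the unmatched ground truth (of its own class when
    ``class_aware``) with the highest IOU, provided that IOU reaches the
    threshold; otherwise it is a false positive.  Each ground truth is matched
    at most once.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError("iou_threshold must lie in (0, 1]")
    if any(p.score is None for p in preds):
        raise ValueError("all predictions must carry a confidence score")
    if iou is None:
        iou = iou_matrix(preds, gts, frame)
    pairs: list[tuple[int, int, float]] = []
    gt_taken = np.zeros(len(gts), dtype=bool)
    for pi in _pred_order(preds, iou):
        best_j, best_iou = -1, 0.0
        for gj in range(len(gts)):
            if gt_taken[gj]:
                continue
            if class_aware and preds[pi].label != gts[gj].label:
                continue
            if iou[pi, gj] > best_iou:
                best_j, best_iou = gj, iou[pi, gj]
        if best_j >= 0 and best_iou >= iou_threshold:
            gt_taken[best_j] = True
            pairs.append((pi, best_j, float(best_iou)))
    matched_preds = {p for p, _, _ in pairs}
    return MatchResult(
        iou_threshold=iou_threshold,
        pairs=pairs,
        unmatched_preds=[i for i in range(len(preds)) if i not in matched_preds],
        unmatched_gts=[j for j in range(len(gts)) if not gt_taken[j]],
    )


def _by_image(
    instances: Sequence[DetectionInstance],
) -> dict[str, list[DetectionInstance]]:
    grouped: dict[str, list[DetectionInstance]] = {}
    for inst in instances:
        grouped.setdefault(inst.image_id, []).append(inst)
    return grouped


def average_precision(
    preds: Sequence[DetectionInstance],
    gts: Sequence[DetectionInstance],
    label: str,
    iou_threshold: float,
    frames: Mapping[str, tuple[int, int]],
) -> APResult:
    """AP for one class at one IOU threshold, pooled over the whole dataset.

    Detections are matched per image, then ranked globally by score; the
    precision envelope is monotonized (each point takes the maximum precision
    at equal-or-higher recall) and AP is the area under that curve.
    """
    gts_l = [g for g in gts if g.label == label]
    if not gts_l:
        raise ValueError(f"no ground truth of class {label!r}")
    preds_l = [p for p in preds if p.label == label]
    gt_groups = _by_image(gts_l)
    flags: list[tuple[float, str, int, bool]] = []  # (score, image, idx, is_tp)
    for image_id, img_preds in _by_image(preds_l).items():
        img_gts = gt_groups.get(image_id, [])
        match = match_instances(
            img_preds, img_gts, iou_threshold, frames[image_id], class_aware=True
        )
        tp_idx = {p for p, _, _ in match.pairs}
        for i, p in enumerate(img_preds):
            flags.append((float(p.score), image_id, i, i in tp_idx))
    if not flags:
        return APResult(label, iou_threshold, np.array([]), np.array([]), 0.0)
    flags.sort(key=lambda t: (-t[0], t[1], t[2]))
    tp = np.cumsum([f[3] for f in flags])
    n_pred = np.arange(1, len(flags) + 1)
    recall = tp / len(gts_l)
    precision = tp / n_pred
    mono = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = np.concatenate([[0.0], recall[:-1]])
    ap = float(np.sum((recall - prev_r) * mono))
    return APResult(label, iou_threshold, recall, precision, ap)


def mean_average_precision(
    preds: Sequence[DetectionInstance],
    gts: Sequence[DetectionInstance],
    frames: Mapping[str, tuple[int, int]],
    thresholds: Sequence[float] = DEFAULT_IOU_THRESHOLDS,
) -> dict:
    """Per-class AP and class-averaged mAP over a grid of IOU thresholds.

    Classes absent from all ground truth are excluded from the average with a
    warning.  Returns ``{"thresholds", "per_class": {label: {t: ap}},
    "map": {t: value}, "curves": {label: {t: APResult}}}``.
    """
    if len(gts) == 0:
        raise ValueError("need at least one ground-truth instance")
    present = [lab for lab in LABELS if any(g.label == lab for g in gts)]
    for lab in LABELS:
        if lab not in present:
            warnings.warn(f"class {lab!r} absent from ground truth; excluded from mAP")
    per_class: dict[str, dict[float, float]] = {lab: {} for lab in present}
    curves: dict[str, dict[float, APResult]] = {lab: {} for lab in present}
    map_table: dict[float, float] = {}
    for t in thresholds:
        t = float(t)
        aps = []
        for lab in present:
            res = average_precision(preds, gts, lab, t, frames)
            per_class[lab][t] = res.ap
            curves[lab][t] = res
            aps.append(res.ap)
        map_table[t] = float(np.mean(aps))
    return {
        "thresholds": [float(t) for t in thresholds],
        "per_class": per_class,
        "map": map_table,
        "curves": curves,
    }


def mean_iou(matches: MatchResult | Sequence[MatchResult]) -> float:
    """Arithmetic mean IOU over true-positive pairs (mask accuracy)."""
    if isinstance(matches, MatchResult):
        matches = [matches]
    ious = [iou for m in matches for _, _, iou in m.pairs]
    if not ious:
        raise ValueError("mean IOU is undefined with zero true-positive pairs")
    return float(np.mean(ious))


def classify_errors(
    preds: Sequence[DetectionInstance],
    gts: Sequence[DetectionInstance],
    frame: tuple[int, int],
    primary_threshold: float = 0.5,
    floor_threshold: float = 0.1,
) -> ErrorTally:
    """Assign unmatched instances to the four detection error types.

    After class-agnostic matching at ``primary_threshold``, the leftovers are
    scanned in priority order, each instance consumed at most once:

    1. *one-as-two*: an unmatched ground truth overlapped (IOU >= floor) by
       two or more unmatched predictions whose union reaches the primary
       threshold against it;
    2. *two-as-one*: an unmatched prediction overlapping two or more remaining
       ground truths at IOU >= floor each;
    3. *partial*: a remaining ground truth with exactly one remaining
       prediction overlapping it, at an IOU in [floor, primary);
    4. *missed*: a remaining ground truth with no remaining prediction
       overlapping it at IOU >= floor.
    """
    if not (0.0 < floor_threshold < primary_threshold <= 1.0):
        raise ValueError("need 0 < floor_threshold < primary_threshold <= 1")
    iou = iou_matrix(preds, gts, frame)
    match = match_instances(
        preds, gts, primary_threshold, frame, class_aware=False, iou=iou
    )
    free_preds = set(match.unmatched_preds)
    free_gts = set(match.unmatched_gts)
    tally = ErrorTally()
    pred_masks = [p.raster(frame).pixels for p in preds]
    gt_masks = [g.raster(frame).pixels for g in gts]

    # 1. one berry detected as two (or more) fragments
    for gj in sorted(free_gts):
        frags = [pi for pi in sorted(free_preds) if iou[pi, gj] >= floor_threshold]
        if len(frags) < 2:
            continue
        union = np.zeros(frame, dtype=bool)
        for pi in frags:
            np.logical_or(union, pred_masks[pi], out=union)
        denom = int(np.logical_or(union, gt_masks[gj]).sum())
        union_iou = int(np.logical_and(union, gt_masks[gj]).sum()) / denom if denom else 0.0
        if union_iou >= primary_threshold:
            tally.one_as_two += 1
            free_gts.discard(gj)
            free_preds.difference_update(frags)

    # 2. two (or more) berries detected as one
    for pi in sorted(free_preds, key=lambda i: (-float(preds[i].score or 0.0), i)):
        covered = [gj for gj in sorted(free_gts) if iou[pi, gj] >= floor_threshold]
        if len(covered) >= 2:
            tally.two_as_one += 1
            free_preds.discard(pi)
            free_gts.difference_update(covered)

    # 3 & 4. partial and missed detections
    for gj in sorted(free_gts):
        over = [pi for pi in sorted(free_preds) if iou[pi, gj] >= floor_threshold]
        if len(over) == 1 and iou[over[0], gj] < primary_threshold:
            tally.partial += 1
            free_preds.discard(over[0])
        elif len(over) == 0:
            tally.missed += 1
    return tally


def evaluate_dataset(
    preds: Sequence[DetectionInstance],
    gts: Sequence[DetectionInstance],
    frames: Mapping[str, tuple[int, int]],
    thresholds: Sequence[float] = DEFAULT_IOU_THRESHOLDS,
    primary_threshold: float = 0.5,
    floor_threshold: float = 0.1,
) -> dict:
    """Full evaluation report: mAP table, per-class AP, mIOU, error tallies."""
    result = mean_average_precision(preds, gts, frames, thresholds)
    pred_groups = _by_image(preds)
    gt_groups = _by_image(gts)
    matches = []
    tally = ErrorTally()
    for image_id, img_gts in gt_groups.items():
        img_preds = pred_groups.get(image_id, [])
        frame = frames[image_id]
        matches.append(
            match_instances(img_preds, img_gts, primary_threshold, frame, class_aware=True)
        )
        tally = tally + classify_errors(
            img_preds, img_gts, frame, primary_threshold, floor_threshold
        )
    try:
        miou = mean_iou(matches)
    except ValueError:
        miou = None
    curves = result.pop("curves")
    report = {
        "thresholds": result["thresholds"],
        "map": {f"{t:.2f}": v for t, v in result["map"].items()},
        "per_class_ap": {
            lab: {f"{t:.2f}": v for t, v in table.items()}
            for lab, table in result["per_class"].items()
        },
        "primary_threshold": primary_threshold,
        "floor_threshold": floor_threshold,
        "error_tally": tally.as_dict(),
        "n_predictions": len(preds),
        "n_ground_truth": len(gts),
        "pr_curves": {
            lab: {
                f"{t:.2f}": {
                    "recall": res.recall.tolist(),
                    "precision": res.precision.tolist(),
                }
                for t, res in table.items()
            }
            for lab, table in curves.items()
        },
    }
    if miou is not None:
        report["mean_iou"] = miou
    return report


def plot_pr_curves(report: dict, path) -> None:
    """Write a precision-recall figure (one panel per class, one line per threshold)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(report["pr_curves"])
    fig, axes = plt.subplots(1, max(len(labels), 1), figsize=(5 * max(len(labels), 1), 4))
    if len(labels) <= 1:
        axes = [axes]
    for ax, lab in zip(axes, labels):
        for t, curve in report["pr_curves"][lab].items():
            r = np.concatenate([[0.0], np.asarray(curve["recall"])])
            p = np.concatenate([[1.0], np.asarray(curve["precision"])])
            ax.plot(r, p, label=f"IOU {t}")
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_title(lab)
        ax.set_xlim(0, 1.02)
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
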