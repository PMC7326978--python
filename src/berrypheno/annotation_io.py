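"""Read/write polygon annotations and detection records.

Three plain-text interchange formats are supported:

* VGG Image Annotator (VIA) 2.x project JSON — polygon regions with a
  per-region maturity attribute.  Both the ``_via_img_metadata`` dialect and
  the flat ``{key: {filename, regions, ...}}`` dialect are accepted on read;
  the flat dialect is written.
* Detection JSON — one record per segmented berry:
  ``{"image": str, "polygon": [[x, y], ...], "label": "mature"|"immature",
  "score": float}`` (``score`` absent for ground truth).  Records are wrapped
  as ``{"instances": [...]}``; a bare list is also accepted on read.
* Ground-truth CSV — per-view rows ``sample_id, cultivar, view, image, N_t,
  N_c`` carrying the manually counted berry and cluster numbers per branch.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .geometry import BinaryMask, GeometryError, PolygonOutline, rasterize

__all__ = [
    "LABELS",
    "AnnotatedRegion",
    "DetectionInstance",
    "CorrectionReport",
    "read_via",
    "write_via",
    "read_detections",
    "write_detections",
    "read_ground_truth",
    "polygon_from_mask",
    "diff_corrections",
]

#: the two berry classes; background is the absence of a region
LABELS = ("mature", "immature")

GROUND_TRUTH_COLUMNS = ("sample_id", "cultivar", "view", "image", "N_t", "N_c")


def _normalize_label(raw: object) -> str | None:
    label = str(raw).strip().lower()
    return label if label in LABELS else None


@dataclass(frozen=True)
class AnnotatedRegion:
    """One manually (or semi-automatically) outlined berry."""

    image_id: str
    outline: PolygonOutline
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass
class DetectionInstance:
    """One berry instance, either predicted or ground truth.

    Predictions carry a confidence ``score`` in [0, 1]; ground truth does not.
    The mask can be given as a polygon outline, a raster, or both.
    """

    image_id: str
    label: str
    score: float | None = None
    polygon: PolygonOutline | None = None
    mask: BinaryMask | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.polygon is None and self.mask is None:
            raise ValueError("instance needs a polygon or a mask")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    def raster(self, frame: tuple[int, int]) -> BinaryMask:
        """Materialize the instance mask on the given (height, width) frame."""
        if self.mask is not None:
            if self.mask.shape != tuple(frame):
                raise GeometryError(
                    f"instance mask frame {self.mask.shape} != requested {tuple(frame)}"
                )
            return self.mask
        return rasterize(self.polygon, frame)


# ---------------------------------------------------------------------------
# VIA project JSON


def _via_metadata(data: Mapping) -> Mapping:
    if "_via_img_metadata" in data:
        return data["_via_img_metadata"]
    entries = {k: v for k, v in data.items() if not str(k).startswith("_via")}
    if all(isinstance(v, Mapping) and "regions" in v for v in entries.values()):
        return entries  # flat dialect (an empty project is a valid project)
    raise ValueError("not a recognizable VIA 2.x project JSON")


def read_via(text: str, label_key: str = "maturity") -> list[AnnotatedRegion]:
    """Parse a VIA 2.x project into annotated regions.

    Non-polygon shapes, unknown maturity labels and degenerate outlines are
    skipped with a warning rather than aborting the whole project.
    """
    meta = _via_metadata(json.loads(text))
    regions: list[AnnotatedRegion] = []
    for key, entry in meta.items():
        image_id = str(entry.get("filename") or key)
        for reg in entry.get("regions", []):
            shape = reg.get("shape_attributes", {})
            if shape.get("name") != "polygon":
                warnings.warn(
                    f"{image_id}: skipping non-polygon region ({shape.get('name')!r})",
                    stacklevel=2,
                )
                continue
            label = _normalize_label(reg.get("region_attributes", {}).get(label_key, ""))
            if label is None:
                warnings.warn(f"{image_id}: skipping region with unknown label", stacklevel=2)
                continue
            try:
                outline = PolygonOutline(
                    np.column_stack([shape["all_points_x"], shape["all_points_y"]])
                )
            except (GeometryError, KeyError) as exc:
                warnings.warn(f"{image_id}: skipping bad polygon ({exc})", stacklevel=2)
                continue
            regions.append(AnnotatedRegion(image_id, outline, label))
    return regions


def write_via(regions: Iterable[AnnotatedRegion], label_key: str = "maturity") -> str:
    """Serialize regions as a flat-dialect VIA 2.x project (round-trip stable)."""
    project: dict[str, dict] = {}
    for reg in regions:
        entry = project.setdefault(
            f"{reg.image_id}-1",
            {"filename": reg.image_id, "size": -1, "regions": [], "file_attributes": {}},
        )
        entry["regions"].append(
            {
                "shape_attributes": {
                    "name": "polygon",
                    "all_points_x": [float(x) for x in reg.outline.vertices[:, 0]],
                    "all_points_y": [float(y) for y in reg.outline.vertices[:, 1]],
                },
                "region_attributes": {label_key: reg.label},
            }
        )
    return json.dumps(project, indent=2)


# ---------------------------------------------------------------------------
# Detection JSON


def read_detections(text: str) -> list[DetectionInstance]:
    """Parse detection JSON records into instances (polygon-backed)."""
    data = json.loads(text)
    records = data["instances"] if isinstance(data, Mapping) else data
    out = []
    for rec in records:
        out.append(
            DetectionInstance(
                image_id=str(rec["image"]),
                label=rec["label"],
                score=rec.get("score"),
                polygon=PolygonOutline(np.asarray(rec["polygon"], dtype=float)),
            )
        )
    return out


def polygon_from_mask(mask: BinaryMask) -> PolygonOutline:
    """Trace the largest connected contour of a raster mask as a polygon.

    Lossy for disconnected masks (only the largest piece is kept) — intended
    for exporting raster-backed detections to the polygon interchange format.
    """
    padded = np.pad(mask.pixels.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise GeometryError("cannot trace contour of empty mask")
    contour = max(contours, key=len) - 1.0  # undo padding; (row, col)
    return PolygonOutline(contour[:, ::-1])


def write_detections(instances: Iterable[DetectionInstance]) -> str:
    """Serialize instances as detection JSON, tracing polygons from rasters when needed."""
    records = []
    for inst in instances:
        poly = inst.polygon if inst.polygon is not None else polygon_from_mask(inst.mask)
        rec: dict = {
            "image": inst.image_id,
            "polygon": [[float(x), float(y)] for x, y in poly.vertices],
            "label": inst.label,
        }
        if inst.score is not None:
            rec["score"] = float(inst.score)
        records.append(rec)
    return json.dumps({"instances": records}, indent=2)


# ---------------------------------------------------------------------------
# Ground-truth CSV


def read_ground_truth(path_or_buf) -> pd.DataFrame:
    """Load the per-view ground-truth table, checking the expected columns."""
    df = pd.read_csv(path_or_buf)
    missing = set(GROUND_TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ground-truth CSV is missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Iterative-annotation correction diff


@dataclass
class CorrectionReport:
    """Tally of what a manual correction pass changed in a generated annotation.

    Every region in the union of both sets is accounted for exactly once:
    paired regions contribute one *unchanged*, *relabeled* or *reshaped* event,
    unpaired generated regions are *removed*, unpaired corrected ones *added*.
    """

    added: int = 0
    removed: int = 0
    relabeled: int = 0
    reshaped: int = 0
    unchanged: int = 0
    per_image: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def total_events(self) -> int:
        return self.added + self.removed + self.relabeled + self.reshaped + self.unchanged


def _outline_iou(a: PolygonOutline, b: PolygonOutline) -> float:
    pa, pb = a.to_shapely(), b.to_shapely()
    union = pa.union(pb).area
    if union <= 0:
        return 0.0
    return pa.intersection(pb).area / union


def diff_corrections(
    generated: Sequence[AnnotatedRegion],
    corrected: Sequence[AnnotatedRegion],
    iou_match_threshold: float = 0.5,
    reshape_iou: float = 0.95,
) -> CorrectionReport:
    """Quantify a manual correction pass over generated annotations.

    Regions are paired greedily per image by descending polygon IOU above
    ``iou_match_threshold``.  A pair with a label change counts as *relabeled*;
    with the same label it is *unchanged* when IOU >= ``reshape_iou`` and
    *reshaped* below.  Unpaired generated regions were *removed*, unpaired
    corrected regions were *added*.
    """
    if not (0.0 < iou_match_threshold <= 1.0):
        raise ValueError("iou_match_threshold must lie in (0, 1]")
    report = CorrectionReport()
    images = sorted(
        {r.image_id for r in generated} | {r.image_id for r in corrected}
    )
    for image_id in images:
        gen = [r for r in generated if r.image_id == image_id]
        cor = [r for r in corrected if r.image_id == image_id]
        candidates = []
        for i, g in enumerate(gen):
            for j, c in enumerate(cor):
                iou = _outline_iou(g.outline, c.outline)
                if iou >= iou_match_threshold:
                    candidates.append((iou, i, j))
        candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
        counts = {"added": 0, "removed": 0, "relabeled": 0, "reshaped": 0, "unchanged": 0}
        used_g: set[int] = set()
        used_c: set[int] = set()
        for iou, i, j in candidates:
            if i in used_g or j in used_c:
                continue
            used_g.add(i)
            used_c.add(j)
            if gen[i].label != cor[j].label:
                counts["relabeled"] += 1
            elif iou >= reshape_iou:
                counts["unchanged"] += 1
            else:
                counts["reshaped"] += 1
        counts["removed"] += len(gen) - len(used_g)
        counts["added"] += len(cor) - len(used_c)
        report.per_image[image_id] = counts
        report.added += counts["added"]
        report.removed += counts["removed"]
        report.relabeled += counts["relabeled"]
        report.reshaped += counts["reshaped"]
        report.unchanged += counts["unchanged"]
    return report
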