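"""Per-view berry traits and their aggregation across the views of a branch.

Three traits are computed from the instances detected in one view of a branch:

* berry count ``N_b`` — the number of detected instances;
* maturity — ``N_m / N_b``, the fraction of detected berries labelled mature;
* compactness — ``A / A_b``, the union area of all berry masks over the area
  of the minimum-area rotated rectangle enclosing them.  The rotated (rather
  than axis-aligned) box makes the value invariant to how the branch happens
  to be oriented in the image.

Branch-level traits are the unweighted means of the per-view values over the
(typically five) views covering the branch.

An objective per-berry maturity call is provided from color alone: the berry
is mature when the majority of its mask pixels have a Hue (0-180 half-degree
scale) in the red/purple ranges (0, 30) or (150, 180); the mask boundary is
first eroded by 10 px to drop background bleed along the outline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

from .annotation_io import DetectionInstance
from .geometry import GeometryError, erode, mask_corner_points, min_area_rect, union_area

__all__ = [
    "MATURE_HUE_RANGES",
    "DEFAULT_EROSION_RADIUS",
    "TraitRecord",
    "SampleTraits",
    "count_berries",
    "maturity_ratio",
    "hue_channel",
    "mature_hue_fraction",
    "hue_maturity",
    "compactness",
    "compute_traits",
    "aggregate_sample",
    "traits_frame",
]

#: Hue intervals (0-180 scale) counted as mature; bounds are strict.
MATURE_HUE_RANGES: tuple[tuple[float, float], ...] = ((0.0, 30.0), (150.0, 180.0))

#: default mask-boundary erosion before reading berry color, in pixels
DEFAULT_EROSION_RADIUS = 10


@dataclass(frozen=True)
class TraitRecord:
    """The three traits (plus their ingredients) for one view of one branch."""

    n_berries: int
    n_mature: int
    maturity: float
    mask_area: int
    box_area: float
    compactness: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_mature <= self.n_berries):
            raise ValueError("need 0 <= N_m <= N_b")
        if not (0.0 < self.compactness <= 1.0 + 1e-12):
            raise ValueError(f"compactness must lie in (0, 1], got {self.compactness}")


@dataclass(frozen=True)
class SampleTraits:
    """Per-branch traits: the per-view records plus their means."""

    sample_id: str
    cultivar: str
    views: tuple[TraitRecord, ...]
    n_true: int | None = None  # manually counted berries on the branch (N_t)
    n_clusters: int | None = None  # destructively counted clusters (N_c)

    def __post_init__(self) -> None:
        if len(self.views) == 0:
            raise ValueError("a sample needs at least one view")

    @property
    def berry_count(self) -> float:
        return float(np.mean([v.n_berries for v in self.views]))

    @property
    def maturity(self) -> float:
        return float(np.mean([v.maturity for v in self.views]))

    @property
    def compactness(self) -> float:
        return float(np.mean([v.compactness for v in self.views]))


def count_berries(instances: Sequence[DetectionInstance]) -> int:
    """N_b: the number of detected berries in the view."""
    return len(instances)


def maturity_ratio(instances: Sequence[DetectionInstance]) -> float:
    """N_m / N_b from the instance labels; undefined (rejected) for an empty view."""
    if len(instances) == 0:
        raise ValueError("maturity is undefined for a view with no detected berries")
    n_mature = sum(1 for inst in instances if inst.label == "mature")
    return n_mature / len(instances)


def hue_channel(image: np.ndarray) -> np.ndarray:
    """Hue of an RGB image on the 0-180 half-degree scale."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    return rgb2hsv(image)[..., 0] * 180.0


def mature_hue_fraction(hues: np.ndarray) -> float:
    """Fraction of pixels whose Hue falls strictly inside a mature range."""
    hues = np.asarray(hues, dtype=float)
    if hues.size == 0:
        raise ValueError("no pixels to classify")
    mature = np.zeros(hues.shape, dtype=bool)
    for lo, hi in MATURE_HUE_RANGES:
        mature |= (hues > lo) & (hues < hi)
    return float(mature.mean())


def hue_maturity(
    image: np.ndarray,
    instance: DetectionInstance,
    erosion_radius: float = DEFAULT_EROSION_RADIUS,
) -> str:
    """Objective per-berry maturity from color alone.

    The instance mask is eroded by ``erosion_radius`` (falling back to the
    original mask if erosion would empty it), and the berry is called mature
    when more than half of the remaining pixels have a mature-range Hue.
    """
    frame = np.asarray(image).shape[:2]
    mask = instance.raster(frame)
    if mask.area == 0:
        raise GeometryError("instance mask is empty within the image frame")
    eroded, _ = erode(mask, erosion_radius)
    hues = hue_channel(image)[eroded.pixels]
    return "mature" if mature_hue_fraction(hues) > 0.5 else "immature"


def compactness(
    instances: Sequence[DetectionInstance], frame: tuple[int, int]
) -> tuple[int, float, float]:
    """(A, A_b, A/A_b) for one view.

    A is the union area of all berry masks (overlap counted once); A_b is the
    area of the minimum rotated rectangle enclosing every member pixel (the
    rectangle encloses pixel squares, via their corners, so A <= A_b always).
    """
    if len(instances) == 0:
        raise ValueError("compactness is undefined for a view with no detected berries")
    masks = [inst.raster(frame) for inst in instances]
    area = union_area(masks)
    if area == 0:
        raise GeometryError("all instance masks are empty")
    rect = min_area_rect(mask_corner_points(masks))
    return area, rect.area, area / rect.area


def compute_traits(
    instances: Sequence[DetectionInstance], frame: tuple[int, int]
) -> TraitRecord:
    """All three traits for one view from its detected instances."""
    n_b = count_berries(instances)
    maturity = maturity_ratio(instances)
    area, box_area, ratio = compactness(instances, frame)
    return TraitRecord(
        n_berries=n_b,
        n_mature=round(maturity * n_b),
        maturity=maturity,
        mask_area=area,
        box_area=box_area,
        compactness=ratio,
    )


def aggregate_sample(
    sample_id: str,
    cultivar: str,
    views: Sequence[TraitRecord],
    n_true: int | None = None,
    n_clusters: int | None = None,
) -> SampleTraits:
    """Average the per-view traits into branch-level traits (unweighted mean)."""
    if len(views) == 0:
        raise ValueError("cannot aggregate an empty list of views")
    return SampleTraits(
        sample_id=sample_id,
        cultivar=cultivar,
        views=tuple(views),
        n_true=n_true,
        n_clusters=n_clusters,
    )


def traits_frame(samples: Sequence[SampleTraits]) -> pd.DataFrame:
    """Tabulate per-view rows plus one ``view='mean'`` row per sample."""
    rows = []
    for s in samples:
        for i, v in enumerate(s.views):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "cultivar": s.cultivar,
                    "view": str(i),
                    "N_b": v.n_berries,
                    "N_m": v.n_mature,
                    "maturity": v.maturity,
                    "A": v.mask_area,
                    "A_b": v.box_area,
                    "compactness": v.compactness,
                }
            )
        rows.append(
            {
                "sample_id": s.sample_id,
                "cultivar": s.cultivar,
                "view": "mean",
                "N_b": s.berry_count,
                "N_m": float(np.mean([v.n_mature for v in s.views])),
                "maturity": s.maturity,
                "A": float(np.mean([v.mask_area for v in s.views])),
                "A_b": float(np.mean([v.box_area for v in s.views])),
                "compactness": s.compactness,
            }
        )
    return pd.DataFrame(rows)
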