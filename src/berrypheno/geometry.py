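"""Raster and polygon primitives shared by the trait, evaluation and synthetic modules.

Conventions
-----------
All coordinates are 0-based image coordinates: ``x`` grows rightward (columns),
``y`` grows downward (rows).  A pixel at row ``r``, column ``c`` occupies the
unit square ``[c, c+1) x [r, r+1)`` and has its center at ``(c + 0.5, r + 0.5)``.

Rasterization follows the pixel-center rule: a pixel belongs to a polygon iff
its center lies inside it.  Centers that fall exactly on the polygon boundary
are resolved half-open (top/left inclusive) by sampling the center nudged by a
tiny positive offset, which makes areas reproducible: the axis-aligned square
with corners (10,10)-(20,20) rasterizes to exactly 100 pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from shapely import minimum_rotated_rectangle as _shapely_min_rect
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "GeometryError",
    "PolygonOutline",
    "BinaryMask",
    "RotatedRect",
    "rasterize",
    "mask_iou",
    "union_area",
    "min_area_rect",
    "mask_corner_points",
    "erode",
]

#: offset used to break boundary ties in the half-open pixel-center rule
_TIE_EPS = 1e-9


class GeometryError(ValueError):
    """An input violates a geometric precondition (degenerate polygon, empty mask...)."""


@dataclass(frozen=True)
class PolygonOutline:
    """A closed simple polygon in image coordinates.

    The last vertex implicitly connects back to the first.  Consecutive
    duplicate vertices (including an explicit closing repeat) are dropped on
    construction; the cleaned polygon must keep at least three distinct
    vertices and a strictly positive area.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise GeometryError("polygon needs an (n>=3, 2) vertex array")
        keep = np.any(np.abs(v - np.roll(v, 1, axis=0)) > 1e-12, axis=1)
        v = v[keep]
        if len(v) < 3 or len(np.unique(np.round(v, 9), axis=0)) < 3:
            raise GeometryError("degenerate polygon: fewer than 3 distinct vertices")
        if self._shoelace(v) <= 0.0:
            raise GeometryError("degenerate polygon: zero area")
        v = np.ascontiguousarray(v)
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)

    @staticmethod
    def _shoelace(v: np.ndarray) -> float:
        x, y = v[:, 0], v[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    @property
    def area(self) -> float:
        """Signed-area magnitude of the outline (shoelace formula)."""
        return self._shoelace(self.vertices)

    def to_shapely(self) -> _ShapelyPolygon:
        poly = _ShapelyPolygon(self.vertices)
        if not poly.is_valid:
            poly = poly.buffer(0)
        return poly

    def __eq__(self, other: object) -> bool:  # array field needs an explicit eq
        if not isinstance(other, PolygonOutline):
            return NotImplemented
        return self.vertices.shape == other.vertices.shape and bool(
            np.allclose(self.vertices, other.vertices)
        )

    def __hash__(self) -> int:
        return hash(self.vertices.tobytes())


@dataclass(eq=False)
class BinaryMask:
    """A boolean membership grid over the image frame."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise GeometryError("mask must be a 2-D grid")
        self.pixels = p.astype(bool, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # (height, width)

    @property
    def area(self) -> int:
        """Number of member pixels."""
        return int(self.pixels.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool(np.array_equal(self.pixels, other.pixels))


@dataclass(frozen=True)
class RotatedRect:
    """A minimum-area enclosing rectangle.

    ``width >= height`` is canonical and ``angle`` is the rectangle orientation
    in degrees modulo 90, in [0, 90) — a rectangle's side directions are only
    defined up to a quarter turn once the side roles are unpinned, so this is
    the tightest canonical form that always exists (an axis-aligned 10x20
    rectangle has angle 0).  ``corners`` holds the four corner points so the
    exact placement is reconstructible.
    """

    center: tuple[float, float]
    width: float
    height: float
    angle: float
    corners: np.ndarray

    def __post_init__(self) -> None:
        if not (self.width >= self.height > 0):
            raise GeometryError("rectangle needs width >= height > 0")
        if not (0.0 <= self.angle < 90.0):
            raise GeometryError("angle must lie in [0, 90)")
        c = np.asarray(self.corners, dtype=float)
        c.setflags(write=False)
        object.__setattr__(self, "corners", c)

    @property
    def area(self) -> float:
        return self.width * self.height


def rasterize(outline: PolygonOutline, frame: tuple[int, int]) -> BinaryMask:
    """Rasterize a polygon onto a ``(height, width)`` frame.

    Pixels whose centers lie inside the polygon become members (half-open rule,
    see module docstring).  Parts of the polygon outside the frame are clipped
    implicitly; a polygon entirely outside rasterizes to an empty mask with a
    warning.
    """
    h, w = int(frame[0]), int(frame[1])
    if h <= 0 or w <= 0:
        raise GeometryError("frame dimensions must be positive")
    v = outline.vertices
    r0 = max(0, int(np.floor(v[:, 1].min())))
    r1 = min(h, int(np.ceil(v[:, 1].max())) + 1)
    c0 = max(0, int(np.floor(v[:, 0].min())))
    c1 = min(w, int(np.ceil(v[:, 0].max())) + 1)
    mask = np.zeros((h, w), dtype=bool)
    if r1 > r0 and c1 > c0:
        cols = np.arange(c0, c1) + 0.5 + _TIE_EPS
        rows = np.arange(r0, r1) + 0.5 + _TIE_EPS
        cx, cy = np.meshgrid(cols, rows)
        pts = np.column_stack([cx.ravel(), cy.ravel()])
        inside = _MplPath(v).contains_points(pts)
        mask[r0:r1, c0:c1] = inside.reshape(r1 - r0, c1 - c0)
    if not mask.any():
        warnings.warn("polygon rasterized to an empty mask (outside frame?)", stacklevel=2)
    return BinaryMask(mask)


def _check_common_frame(masks: Sequence[BinaryMask]) -> tuple[int, int]:
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise GeometryError(f"masks live on different frames: {sorted(shapes)}")
    return shapes.pop()


def mask_iou(a: BinaryMask, b: BinaryMask) -> float:
    """Intersection over union of two masks on the same frame.

    Rejects mismatched frames and the degenerate both-empty case (the ratio is
    undefined there, not zero).
    """
    _check_common_frame([a, b])
    union = int(np.logical_or(a.pixels, b.pixels).sum())
    if union == 0:
        raise GeometryError("IOU undefined: both masks are empty")
    inter = int(np.logical_and(a.pixels, b.pixels).sum())
    return inter / union


def union_area(masks: Sequence[BinaryMask]) -> int:
    """Pixel count of the union of masks; overlapping pixels count once."""
    if len(masks) == 0:
        raise GeometryError("union_area needs at least one mask")
    _check_common_frame(masks)
    out = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        np.logical_or(out, m.pixels, out=out)
    return int(out.sum())


def mask_corner_points(masks: BinaryMask | Sequence[BinaryMask]) -> np.ndarray:
    """Corner coordinates of the member pixels of one or more masks.

    Each member pixel at row r / column c contributes its four unit-square
    corners (c, r) .. (c+1, r+1).  Only boundary pixels are expanded — interior
    pixel corners can never lie on the convex hull — which keeps the point set
    small for large blobs.
    """
    if isinstance(masks, BinaryMask):
        masks = [masks]
    _check_common_frame(list(masks))
    union = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        np.logical_or(union, m.pixels, out=union)
    if not union.any():
        raise GeometryError("no member pixels")
    boundary = union & ~ndimage.binary_erosion(union)
    rc = np.argwhere(boundary).astype(float)  # (n, 2) rows, cols
    offsets = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    pts = (rc[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    pts = np.unique(pts, axis=0)
    return pts[:, ::-1].copy()  # (x, y) order


def min_area_rect(points: Iterable[Sequence[float]] | np.ndarray) -> RotatedRect:
    """Minimum-area enclosing rectangle over all orientations.

    The optimum is flush with a convex-hull edge (rotating-calipers property),
    so the search reduces to the hull edges; rotating the input by any angle
    yields a rectangle of equal area up to floating-point tolerance.
    """
    pts = np.asarray(list(points) if not isinstance(points, np.ndarray) else points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise GeometryError("need at least 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise GeometryError("collinear or degenerate point set") from exc
    hull_pts = pts[hull.vertices]
    rect = _shapely_min_rect(_ShapelyPolygon(hull_pts))
    if rect.geom_type != "Polygon":
        raise GeometryError("degenerate point set: no enclosing rectangle")
    corners = np.asarray(rect.exterior.coords)[:4]
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    l1, l2 = float(np.hypot(*e1)), float(np.hypot(*e2))
    width, height = (l1, l2) if l1 >= l2 else (l2, l1)
    long_edge = e1 if l1 >= l2 else e2
    angle = float(np.degrees(np.arctan2(long_edge[1], long_edge[0]))) % 90.0
    center = corners.mean(axis=0)
    return RotatedRect(
        center=(float(center[0]), float(center[1])),
        width=width,
        height=height,
        angle=angle,
        corners=corners,
    )


def _disk_footprint(radius: int) -> np.ndarray:
    # Euclidean disk structuring element: offsets within `radius` of the origin.
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx * xx + yy * yy) <= r * r


def erode(mask: BinaryMask, radius: float) -> tuple[BinaryMask, bool]:
    """Morphological erosion with a Euclidean disk structuring element.

    Returns ``(mask, eroded)``.  If erosion would wipe the mask out entirely
    the *original* mask is returned with ``eroded=False`` so that small objects
    still get a color decision downstream.
    """
    if radius < 0:
        raise GeometryError("erosion radius must be >= 0")
    r = int(round(radius))
    if r == 0:
        return BinaryMask(mask.pixels.copy()), True
    out = ndimage.binary_erosion(mask.pixels, structure=_disk_footprint(r))
    if not out.any():
        return mask, False
    return BinaryMask(out), True
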