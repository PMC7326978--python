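"""Synthetic berry-cluster scenes with exact ground truth.

The generator renders a fruit-bearing branch as clustered colored disks on a
plain background, the way a cropped field photo of a blueberry branch against
an artificial backdrop reduces to: 5-25 berries grouped in 1-4 clusters,
mature berries in the red/purple Hue ranges (0,30)/(150,180) and immature
ones in the green range (35,100) on the 0-180 scale, with partial occlusion
produced by z-ordering (a berry's visible mask is its disk minus the disks in
front of it).  A branch sample is a set of views that share the same berries,
labels and cluster count but re-draw placement and z-order, emulating the
five camera angles around a branch.

``perturb_to_detections`` degrades the exact ground truth into detector-like
output, reproducing the four qualitative detection failure modes (drop a
berry, split one into two fragments, merge two neighbours into one blob,
shift a mask so only part overlaps) plus label noise, with scores sampled
higher for unperturbed instances.

Everything is bit-exactly reproducible from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage

from .annotation_io import DetectionInstance
from .geometry import BinaryMask, GeometryError, PolygonOutline
from .traits import TraitRecord, compute_traits

__all__ = [
    "SceneParams",
    "BerrySpec",
    "SceneBerry",
    "SyntheticScene",
    "BranchSample",
    "DetectionNoise",
    "generate_scene",
    "generate_branch_sample",
    "perturb_to_detections",
]


def _as_range(value, name: str) -> tuple[int, int]:
    if np.isscalar(value):
        lo = hi = int(value)
    else:
        lo, hi = int(value[0]), int(value[1])
    if not (1 <= lo <= hi):
        raise ValueError(f"{name} must be a positive int or (lo, hi) range")
    return lo, hi


@dataclass(frozen=True)
class SceneParams:
    """Knobs of the scene generator.

    Defaults emulate the stated imaging conditions at desk scale: a branch of
    5-25 partially occluding berries in 1-4 clusters photographed against a
    brown artificial background, with roughly half the berries mature.
    """

    image_size: tuple[int, int] = (320, 320)  # (height, width) pixels
    berry_count: int | tuple[int, int] = (5, 25)
    berry_radius: float = 13.0  # mean radius, pixels
    berry_radius_sd: float = 2.0
    cluster_count: int | tuple[int, int] = (1, 4)
    cluster_spread: float = 1.8  # berry jitter sd within a cluster, x mean radius
    overlap_intensity: float = 0.25  # 0 = disjoint berries, ->1 = heavy occlusion
    maturity_prob: float = 0.55
    mature_hue: tuple[tuple[float, float], ...] = ((4.0, 28.0), (152.0, 176.0))
    immature_hue: tuple[float, float] = (38.0, 98.0)
    saturation: tuple[float, float] = (0.55, 0.95)
    value: tuple[float, float] = (0.35, 0.85)
    background_rgb: tuple[int, int, int] = (151, 123, 93)  # brown backdrop
    color_noise: float = 0.0  # gaussian sd on 0-255 channels

    def __post_init__(self) -> None:
        _as_range(self.berry_count, "berry_count")
        _as_range(self.cluster_count, "cluster_count")
        if not (0.0 <= self.overlap_intensity < 1.0):
            raise ValueError("overlap_intensity must lie in [0, 1)")
        if not (0.0 <= self.maturity_prob <= 1.0):
            raise ValueError("maturity_prob must lie in [0, 1]")
        if self.berry_radius <= 2 or self.berry_radius_sd < 0:
            raise ValueError("berry radius must be > 2 px with sd >= 0")
        if self.color_noise < 0:
            raise ValueError("color_noise must be >= 0")


@dataclass(frozen=True)
class BerrySpec:
    """Intrinsic berry properties shared across the views of a branch."""

    radius: float
    label: str
    hue: float  # 0-180 scale
    saturation: float
    value: float


@dataclass
class SceneBerry:
    """One rendered berry: placement, z-rank and visibility ground truth."""

    index: int
    spec: BerrySpec
    center: tuple[float, float]  # (x, y)
    z: int  # larger = nearer the camera
    outline: PolygonOutline  # full (unoccluded) disk outline
    visible_mask: BinaryMask  # after z-order occlusion; may be empty

    @property
    def visible(self) -> bool:
        return self.visible_mask.area > 0

    @property
    def label(self) -> str:
        return self.spec.label


@dataclass
class SyntheticScene:
    """One rendered view with exact per-berry ground truth."""

    image_id: str
    image: np.ndarray  # (H, W, 3) uint8
    berries: list[SceneBerry]
    params: SceneParams
    seed: int | None = None

    @property
    def frame(self) -> tuple[int, int]:
        return self.image.shape[:2]

    @property
    def n_total(self) -> int:
        return len(self.berries)

    @property
    def n_mature(self) -> int:
        return sum(1 for b in self.berries if b.label == "mature")

    def ground_truth_instances(self) -> list[DetectionInstance]:
        """Visible berries as ground-truth detection instances (no scores)."""
        return [
            DetectionInstance(
                image_id=self.image_id,
                label=b.label,
                mask=b.visible_mask,
                polygon=b.outline,
            )
            for b in self.berries
            if b.visible
        ]

    def trait_record(self) -> TraitRecord:
        """Traits computed from the visible ground-truth masks."""
        return compute_traits(self.ground_truth_instances(), self.frame)


@dataclass
class BranchSample:
    """A branch imaged from several views, with branch-level ground truth."""

    sample_id: str
    cultivar: str
    scenes: list[SyntheticScene]
    n_total: int  # N_t: berries on the branch
    n_clusters: int  # N_c

    @property
    def n_mature(self) -> int:
        return self.scenes[0].n_mature


# ---------------------------------------------------------------------------
# generation


def _draw_specs(rng: np.random.Generator, n: int, params: SceneParams) -> list[BerrySpec]:
    specs = []
    m_lens = [hi - lo for lo, hi in params.mature_hue]
    m_probs = np.array(m_lens) / sum(m_lens)
    for _ in range(n):
        mature = rng.random() < params.maturity_prob
        if mature:
            lo, hi = params.mature_hue[rng.choice(len(params.mature_hue), p=m_probs)]
        else:
            lo, hi = params.immature_hue
        specs.append(
            BerrySpec(
                radius=float(
                    np.clip(
                        rng.normal(params.berry_radius, params.berry_radius_sd),
                        3.0,
                        params.berry_radius * 2.0,
                    )
                ),
                label="mature" if mature else "immature",
                hue=float(rng.uniform(lo, hi)),
                saturation=float(rng.uniform(*params.saturation)),
                value=float(rng.uniform(*params.value)),
            )
        )
    return specs


def _place(
    rng: np.random.Generator,
    specs: Sequence[BerrySpec],
    n_clusters: int,
    params: SceneParams,
) -> np.ndarray:
    """Berry centers: cluster centers plus jitter; disjoint placement at overlap 0."""
    h, w = params.image_size
    margin = max(s.radius for s in specs) + 2.0
    if 2 * margin >= min(h, w):
        raise GeometryError("berries cannot fit in the frame")
    spread = params.cluster_spread * params.berry_radius
    if params.overlap_intensity > 0:
        spread *= 1.0 - 0.75 * params.overlap_intensity
    cx = rng.uniform(margin + spread / 2, w - margin - spread / 2, size=n_clusters)
    cy = rng.uniform(margin + spread / 2, h - margin - spread / 2, size=n_clusters)
    assignment = rng.integers(0, n_clusters, size=len(specs))
    centers = np.zeros((len(specs), 2))
    for i, spec in enumerate(specs):
        k = assignment[i]
        placed = False
        local_spread = spread
        for attempt in range(300):
            x = float(np.clip(rng.normal(cx[k], local_spread), margin, w - margin))
            y = float(np.clip(rng.normal(cy[k], local_spread), margin, h - margin))
            if params.overlap_intensity > 0:
                placed = True
            else:
                d = np.hypot(centers[:i, 0] - x, centers[:i, 1] - y)
                radii = np.array([specs[j].radius for j in range(i)])
                placed = bool(np.all(d > radii + spec.radius + 1.0))
            if placed:
                centers[i] = (x, y)
                break
            if attempt and attempt % 75 == 0:
                local_spread *= 1.6  # widen the search before giving up
        if not placed:
            raise GeometryError("could not place all berries without overlap")
    return centers


def _circle_outline(center: tuple[float, float], radius: float, n_vertices: int = 64) -> PolygonOutline:
    # circumscribed polygon so every disk pixel stays inside the outline
    r = radius / np.cos(np.pi / n_vertices)
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return PolygonOutline(
        np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])
    )


def generate_scene(
    params: SceneParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    berry_specs: Sequence[BerrySpec] | None = None,
    n_clusters: int | None = None,
    image_id: str = "scene",
) -> SyntheticScene:
    """Render one view: place berries, z-order them, paint front-to-back."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if berry_specs is None:
        lo, hi = _as_range(params.berry_count, "berry_count")
        berry_specs = _draw_specs(rng, int(rng.integers(lo, hi + 1)), params)
    if n_clusters is None:
        lo, hi = _as_range(params.cluster_count, "cluster_count")
        n_clusters = int(rng.integers(lo, hi + 1))
    centers = _place(rng, berry_specs, n_clusters, params)
    n = len(berry_specs)
    z_order = rng.permutation(n)  # z_order[i] = z rank of berry i

    h, w = params.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    owner = np.full((h, w), -1, dtype=np.int32)
    # paint back to front; the front-most berry owns each pixel
    for i in np.argsort(z_order):
        cxi, cyi = centers[i]
        r = berry_specs[i].radius
        disk = (xx + 0.5 - cxi) ** 2 + (yy + 0.5 - cyi) ** 2 <= r * r
        owner[disk] = i

    colors = np.array(
        [
            hsv_to_rgb([s.hue / 180.0, s.saturation, s.value]) * 255.0
            for s in berry_specs
        ]
    )
    image = np.empty((h, w, 3), dtype=float)
    image[:] = np.asarray(params.background_rgb, dtype=float)
    for i in range(n):
        image[owner == i] = colors[i]
    if params.color_noise > 0:
        image += rng.normal(0.0, params.color_noise, size=image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)

    berries = [
        SceneBerry(
            index=i,
            spec=berry_specs[i],
            center=(float(centers[i, 0]), float(centers[i, 1])),
            z=int(z_order[i]),
            outline=_circle_outline(centers[i], berry_specs[i].radius),
            visible_mask=BinaryMask(owner == i),
        )
        for i in range(n)
    ]
    return SyntheticScene(image_id=image_id, image=image, berries=berries, params=params, seed=seed)


def generate_branch_sample(
    params: SceneParams,
    n_views: int = 5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
    cultivar: str = "synthetic",
) -> BranchSample:
    """A branch of berries re-imaged ``n_views`` times.

    Berry count, radii, labels, colors and cluster count are drawn once and
    shared by all views; placement and z-order are re-drawn per view, so
    visibility (occlusion) varies while N_t and N_c stay fixed.
    """
    if n_views < 1:
        raise ValueError("need at least one view")
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = _as_range(params.berry_count, "berry_count")
    n = int(rng.integers(lo, hi + 1))
    lo_c, hi_c = _as_range(params.cluster_count, "cluster_count")
    n_clusters = int(rng.integers(lo_c, hi_c + 1))
    specs = _draw_specs(rng, n, params)
    scenes = [
        generate_scene(
            params,
            rng=rng,
            berry_specs=specs,
            n_clusters=n_clusters,
            image_id=f"{sample_id}_view{v}",
        )
        for v in range(n_views)
    ]
    return BranchSample(
        sample_id=sample_id,
        cultivar=cultivar,
        scenes=scenes,
        n_total=n,
        n_clusters=n_clusters,
    )


# ---------------------------------------------------------------------------
# detector-like perturbations


@dataclass(frozen=True)
class DetectionNoise:
    """Per-instance perturbation rates (probabilities, must sum to <= 1)."""

    drop: float = 0.0
    split: float = 0.0
    merge: float = 0.0
    jitter: float = 0.0
    relabel: float = 0.0
    jitter_px: float = 12.0  # translation magnitude of a jittered mask

    def __post_init__(self) -> None:
        rates = (self.drop, self.split, self.merge, self.jitter, self.relabel)
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if sum(rates) > 1.0 + 1e-12:
            raise ValueError("perturbation rates must sum to <= 1 per instance")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")


def _flip(label: str) -> str:
    return "immature" if label == "mature" else "mature"


def _shift_mask(mask: np.ndarray, dx: int, dy: int) -> np.ndarray:
    out = np.zeros_like(mask)
    h, w = mask.shape
    ys = slice(max(0, dy), min(h, h + dy))
    xs = slice(max(0, dx), min(w, w + dx))
    ys_src = slice(max(0, -dy), min(h, h - dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    out[ys, xs] = mask[ys_src, xs_src]
    return out


def _split_mask(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Split at the median member column, discarding a 3-px seam.

    Each fragment holds strictly less than half of the source pixels, so a
    fragment can never reach IOU 0.5 against the source berry, while the two
    together still cover most of it.
    """
    cols = np.nonzero(mask)[1]
    cm = int(np.median(cols))
    col_idx = np.arange(mask.shape[1])[None, :]
    left = mask & (col_idx < cm - 1)
    right = mask & (col_idx > cm + 1)
    if not left.any() or not right.any():
        return None
    return left, right


def perturb_to_detections(
    scene: SyntheticScene,
    noise: DetectionNoise,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[DetectionInstance]:
    """Degrade ground truth into detector-like predictions with scores.

    Each visible berry is independently dropped, split into two fragments,
    merged with its nearest not-yet-processed neighbour (as one dilated blob),
    translated by ``jitter_px``, relabeled, or kept.  Unperturbed instances
    get scores in [0.85, 1); perturbed ones in [0.4, 0.8).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    visible = [b for b in scene.berries if b.visible]
    edges = np.cumsum([noise.drop, noise.split, noise.merge, noise.jitter, noise.relabel])
    consumed: set[int] = set()
    detections: list[DetectionInstance] = []

    def _hi_score() -> float:
        return float(rng.uniform(0.85, 0.999))

    def _lo_score() -> float:
        return float(rng.uniform(0.4, 0.8))

    for i, berry in enumerate(visible):
        if i in consumed:
            continue
        u = rng.random()
        mode = int(np.searchsorted(edges, u, side="right"))  # 5 = keep
        mask = berry.visible_mask.pixels
        if mode == 0:  # drop -> missed detection
            continue
        if mode == 1:  # split -> one berry detected as two
            frags = _split_mask(mask)
            if frags is not None:
                for frag in frags:
                    detections.append(
                        DetectionInstance(
                            image_id=scene.image_id,
                            label=berry.label,
                            score=_lo_score(),
                            mask=BinaryMask(frag),
                        )
                    )
                continue
            mode = 5  # too narrow to split: keep instead
        if mode == 2:  # merge -> two berries detected as one
            partners = [
                j
                for j in range(i + 1, len(visible))
                if j not in consumed and visible[j].visible
            ]
            if partners:
                dists = [
                    np.hypot(
                        visible[j].center[0] - berry.center[0],
                        visible[j].center[1] - berry.center[1],
                    )
                    for j in partners
                ]
                j = partners[int(np.argmin(dists))]
                consumed.add(j)
                blob = np.logical_or(mask, visible[j].visible_mask.pixels)
                # a merged detection is one sloppy blob: dilate by ~0.3x the
                # pair's mean radius so the blob is strictly bigger than either
                # berry and cannot simply match one of them
                r_dil = max(2, int(round(0.3 * (berry.spec.radius + visible[j].spec.radius) / 2)))
                yy, xx = np.mgrid[-r_dil : r_dil + 1, -r_dil : r_dil + 1]
                blob = ndimage.binary_dilation(blob, structure=(xx**2 + yy**2) <= r_dil**2)
                detections.append(
                    DetectionInstance(
                        image_id=scene.image_id,
                        label=berry.label,
                        score=_lo_score(),
                        mask=BinaryMask(blob),
                    )
                )
                continue
            mode = 5  # nobody left to merge with: keep instead
        if mode == 3 and noise.jitter_px > 0:  # jitter -> partial overlap
            theta = rng.uniform(0.0, 2.0 * np.pi)
            # a displaced detection still covers part of its berry: cap the
            # shift at about one radius so the overlap does not vanish
            d = min(noise.jitter_px * rng.uniform(0.9, 1.3), 1.1 * berry.spec.radius)
            shifted = _shift_mask(
                mask, int(round(d * np.cos(theta))), int(round(d * np.sin(theta)))
            )
            if shifted.any():
                detections.append(
                    DetectionInstance(
                        image_id=scene.image_id,
                        label=berry.label,
                        score=_lo_score(),
                        mask=BinaryMask(shifted),
                    )
                )
            continue
        if mode == 4:  # relabel
            detections.append(
                DetectionInstance(
                    image_id=scene.image_id,
                    label=_flip(berry.label),
                    score=_hi_score(),
                    mask=BinaryMask(mask.copy()),
                )
            )
            continue
        # keep (also the fallback for degenerate split/merge and zero jitter)
        detections.append(
            DetectionInstance(
                image_id=scene.image_id,
                label=berry.label,
                score=_hi_score(),
                mask=BinaryMask(mask.copy()),
            )
        )
    return detections
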