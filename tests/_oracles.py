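"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths: the rectangle oracle
sweeps orientations on a fine grid, the rasterization oracle asks shapely
about every pixel center, and the AP oracle re-derives the precision-recall
curve by enumerating every prefix of the score-sorted detections with a naive
re-matching per prefix.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Point, Polygon


def min_rect_area_sweep(points: np.ndarray, step_deg: float = 0.01) -> float:
    """Minimum enclosing-rectangle area by brute-force angle sweep over [0, 90)."""
    pts = np.asarray(points, dtype=float)
    theta = np.deg2rad(np.arange(0.0, 90.0, step_deg))
    c, s = np.cos(theta), np.sin(theta)
    x, y = pts[:, 0], pts[:, 1]
    xr = np.outer(x, c) + np.outer(y, s)
    yr = -np.outer(x, s) + np.outer(y, c)
    areas = (xr.max(axis=0) - xr.min(axis=0)) * (yr.max(axis=0) - yr.min(axis=0))
    return float(areas.min())


def rasterize_count_oracle(vertices: np.ndarray, frame: tuple[int, int]) -> int:
    """Count pixel centers inside the polygon, one shapely query per pixel."""
    poly = Polygon(vertices)
    h, w = frame
    count = 0
    for r in range(h):
        for c in range(w):
            if poly.contains(Point(c + 0.5, r + 0.5)):
                count += 1
    return count


def _greedy_tp_count(order, iou, taken_template, thr):
    taken = list(taken_template)
    tp = 0
    for pi in order:
        best_j, best = -1, 0.0
        for gj in range(len(taken)):
            if not taken[gj] and iou[pi][gj] > best:
                best_j, best = gj, iou[pi][gj]
        if best_j >= 0 and best >= thr:
            taken[best_j] = True
            tp += 1
    return tp


def ap_prefix_oracle(scores, iou, n_gt: int, thr: float) -> float:
    """AP by enumerating every prefix of the score-sorted detections.

    ``iou`` is a (n_pred, n_gt) nested list restricted to one class on one
    image.  Each prefix is re-matched from scratch; the resulting PR points
    are monotonized and integrated step-wise.
    """
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    recalls, precisions = [], []
    for k in range(1, len(order) + 1):
        tp = _greedy_tp_count(order[:k], iou, [False] * n_gt, thr)
        recalls.append(tp / n_gt)
        precisions.append(tp / k)
    # monotonize from the right
    for i in range(len(precisions) - 2, -1, -1):
        precisions[i] = max(precisions[i], precisions[i + 1])
    ap, prev_r = 0.0, 0.0
    for r, p in zip(recalls, precisions):
        ap += (r - prev_r) * p
        prev_r = r
    return ap


def ols_normal_equations(x, y):
    """Closed-form OLS intercept/slope via the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    A = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    return float(beta[0]), float(beta[1])
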