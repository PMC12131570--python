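"""Kernel-row structure of maize ears from detected kernel centroids.

A single-view photograph of an ear shows kernels arranged in a regular
lattice: long rows along the ear axis, repeated across it. Given kernel
center points from any detector (or a CSV), the ear's long axis is recovered
by principal component analysis, rows are found by 1-D K-means clustering of
the cross-axis coordinate with silhouette-based selection of the row count,
and per-row kernel counts are tallied.

Point sets here use (x, y) coordinate order, matching the ``x,y`` CSV header
accepted for externally detected centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import DegenerateGeometryError, InvalidParameterError

__all__ = [
    "AlignedPoints",
    "RowFeatures",
    "pca_align",
    "cluster_rows",
    "extract_row_features",
    "silhouette_1d",
]


@dataclass(frozen=True)
class AlignedPoints:
    """Point set rotated so the ear long axis is the x-axis."""

    points: np.ndarray  # (n, 2), (x, y); x = along-ear, y = cross-axis
    rotation_deg: float  # applied rotation (counter-clockwise, math convention)
    mean: np.ndarray  # (2,) centroid removed before rotation


@dataclass(frozen=True)
class RowFeatures:
    """Visible-face kernel-row summary of one ear."""

    visible_kernel_count: int
    visible_row_count: int
    kernels_per_row: tuple[int, ...]  # ordered along the cross-axis
    mean_kernels_per_row: float

    def __post_init__(self) -> None:
        if sum(self.kernels_per_row) != self.visible_kernel_count:
            raise InvalidParameterError("kernels_per_row must sum to the kernel count")
        if len(self.kernels_per_row) != self.visible_row_count or self.visible_row_count < 1:
            raise InvalidParameterError("row count must match kernels_per_row length")

    def to_dict(self) -> dict:
        return {
            "visible_kernel_count": self.visible_kernel_count,
            "visible_row_count": self.visible_row_count,
            "kernels_per_row": list(self.kernels_per_row),
            "mean_kernels_per_row": self.mean_kernels_per_row,
        }


def pca_align(points: np.ndarray) -> AlignedPoints:
    """Center a kernel point set and rotate its principal axis onto x.

    The rotation sign is normalized so that, along the new x-axis, the span
    ahead of the first point (toward +x) is maximal — a deterministic
    convention making repeated runs comparable.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise InvalidParameterError("need an (n >= 2, 2) point array")
    if not np.isfinite(pts).all():
        raise InvalidParameterError("points must be finite")
    mean = pts.mean(axis=0)
    centered = pts - mean
    if np.allclose(centered, 0):
        raise DegenerateGeometryError("all points coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    e1 = vt[0]
    u = centered @ e1
    if (u.max() - u[0]) < (u[0] - u.min()):
        e1 = -e1
        u = -u
    e2 = np.asarray([-e1[1], e1[0]])  # proper rotation (det = +1)
    aligned = np.column_stack([u, centered @ e2])
    rotation_deg = float(np.degrees(np.arctan2(e1[1], e1[0])))
    return AlignedPoints(points=aligned, rotation_deg=-rotation_deg, mean=mean)


def _sorted_prefix(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = np.sort(vals)
    return s, np.concatenate([[0.0], np.cumsum(s)])


def _mean_abs_dev(x: np.ndarray, sorted_vals: np.ndarray, prefix: np.ndarray) -> np.ndarray:
    """Mean |x - v| over v in sorted_vals, vectorized over query x."""
    m = len(sorted_vals)
    idx = np.searchsorted(sorted_vals, x)
    left_sum = prefix[idx]
    right_sum = prefix[m] - left_sum
    return (x * idx - left_sum + right_sum - x * (m - idx)) / m


def silhouette_1d(y: np.ndarray, labels: np.ndarray) -> float:
    """Exact mean silhouette coefficient for 1-D data.

    Uses per-cluster sorted prefix sums so each point's mean distance to a
    cluster costs O(log n); overall O(n k log n) versus the O(n^2) of the
    generic pairwise computation.
    """
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise InvalidParameterError("silhouette needs at least 2 clusters")
    stats = {c: _sorted_prefix(y[labels == c]) for c in uniq}
    sizes = {c: int((labels == c).sum()) for c in uniq}
    s = np.zeros(len(y))
    for c in uniq:
        in_c = labels == c
        x = y[in_c]
        m = sizes[c]
        sv, pf = stats[c]
        if m == 1:
            s[in_c] = 0.0  # singleton convention
            continue
        a = _mean_abs_dev(x, sv, pf) * m / (m - 1)  # exclude self (distance 0)
        b = np.full(len(x), np.inf)
        for c2 in uniq:
            if c2 == c:
                continue
            sv2, pf2 = stats[c2]
            b = np.minimum(b, _mean_abs_dev(x, sv2, pf2))
        s[in_c] = (b - a) / np.maximum(a, b)
    return float(np.nanmean(s))


def cluster_rows(
    aligned_points: np.ndarray | AlignedPoints,
    k_min: int = 4,
    k_max: int = 24,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[np.ndarray, int]:
    """Cluster kernels into rows by 1-D K-means on the cross-axis coordinate.

    For each candidate row count k in [k_min, k_max], runs K-means
    (k-means++ initialization, ``n_init`` restarts) on the y coordinate and
    scores the partition by mean silhouette; the k with the best silhouette
    wins (ties to the smaller k). k = 1 is only allowed when k_max = 1.

    Returns (row assignment per point, chosen k); deterministic given seed.
    """
    pts = aligned_points.points if isinstance(aligned_points, AlignedPoints) else aligned_points
    pts = np.asarray(pts, dtype=float)
    y = pts[:, 1] if pts.ndim == 2 else pts
    if k_min < 1 or k_min > k_max:
        raise InvalidParameterError("need 1 <= k_min <= k_max")
    n_distinct = len(np.unique(y))
    k_hi = min(k_max, n_distinct)
    k_lo = min(k_min, k_hi)
    if k_hi == 1 or k_max == 1:
        return np.zeros(len(y), dtype=int), 1
    k_lo = max(k_lo, 2)  # silhouette model selection needs >= 2 clusters
    best = None
    ycol = y.reshape(-1, 1)
    for k in range(k_lo, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, init="k-means++")
        labels = km.fit_predict(ycol)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_1d(y, labels)
        if best is None or score > best[0] + 1e-12:
            best = (score, k, labels)
    if best is None:
        return np.zeros(len(y), dtype=int), 1
    _, k, labels = best
    return labels, k


def extract_row_features(
    assignments: np.ndarray, points: np.ndarray | AlignedPoints
) -> RowFeatures:
    """Tally kernels per row, rows ordered by mean cross-axis coordinate."""
    pts = points.points if isinstance(points, AlignedPoints) else np.asarray(points, dtype=float)
    assignments = np.asarray(assignments)
    if len(assignments) != len(pts):
        raise InvalidParameterError("one assignment per point is required")
    uniq = np.unique(assignments)
    means = [(float(pts[assignments == c, 1].mean()), c) for c in uniq]
    order = [c for _, c in sorted(means)]
    counts = tuple(int((assignments == c).sum()) for c in order)
    total = int(len(pts))
    return RowFeatures(
        visible_kernel_count=total,
        visible_row_count=len(counts),
        kernels_per_row=counts,
        mean_kernels_per_row=float(total / len(counts)),
    )
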