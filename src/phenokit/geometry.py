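"""Axis and angle computations for spikelet and flag-leaf phenotyping.

Contents: robust major-axis fitting (RANSAC over two-point hypotheses with a
total-least-squares refit), polynomial ear-axis regression in a
PCA-rotated frame, Zhang-Suen skeletonization of binary shapes, and the
vertex/axis angle computations behind flag-leaf and spikelet angle traits.

Angles are reported in degrees, 0 deg = parallel. Spikelet-to-axis angles
are folded to [0, 90] since chirality (which side of the rachis a spikelet
sits on) is not distinguished.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    InvalidParameterError,
    OutOfDomainError,
)

__all__ = [
    "LineModel",
    "PolyAxis",
    "KeypointTriple",
    "ransac_major_axis",
    "total_least_squares_line",
    "fit_ear_axis",
    "zhang_suen_thin",
    "angle_at_vertex",
    "flag_leaf_angle",
    "spikelet_angle",
]


def _normalize_direction(d: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(d)
    if n == 0:
        raise DegenerateGeometryError("zero-length direction")
    d = d / n
    if d[0] < 0 or (d[0] == 0 and d[1] < 0):
        d = -d
    return d


@dataclass(frozen=True)
class LineModel:
    """A fitted 2-D line: a point on the line plus a unit direction.

    The direction sign is normalized (non-negative first component; ties
    broken toward a non-negative second component).
    """

    point: np.ndarray  # (2,) (row, col)
    direction: np.ndarray  # (2,) unit
    inlier_count: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(
            self, "direction", _normalize_direction(np.asarray(self.direction, dtype=float))
        )


@dataclass(frozen=True)
class PolyAxis:
    """Polynomial curve fitted in a PCA-rotated frame.

    The independent coordinate ``u`` runs along the principal direction of
    the fitted points; the polynomial gives the transverse coordinate
    ``v = poly(u)``. ``rotation`` columns are the (u, v) basis vectors in
    image (row, col) coordinates and ``mean`` is the centroid subtracted
    before rotation.
    """

    degree: int
    coefficients: np.ndarray  # highest power first (np.polyval order)
    domain: tuple[float, float]  # [u_min, u_max]
    rotation: np.ndarray  # (2, 2); columns = u-axis, v-axis in (row, col)
    mean: np.ndarray  # (2,)
    residual_rms: float

    def project(self, point: np.ndarray) -> float:
        """Axis coordinate u of a point (projection onto the principal axis)."""
        rel = np.asarray(point, dtype=float) - self.mean
        return float(rel @ self.rotation[:, 0])

    def evaluate(self, u: float | np.ndarray) -> np.ndarray:
        """Curve point(s) in image coordinates at axis coordinate(s) u."""
        u = np.asarray(u, dtype=float)
        v = np.polyval(self.coefficients, u)
        uv = np.stack([u, v], axis=-1)
        return uv @ self.rotation.T + self.mean

    def tangent_at(self, u: float) -> np.ndarray:
        """Unit tangent of the curve at axis coordinate u, in image coords."""
        dv = np.polyval(np.polyder(self.coefficients), u)
        t = self.rotation @ np.asarray([1.0, float(dv)])
        return _normalize_direction(t)

    def in_domain(self, u: float, tol_frac: float = 0.05) -> bool:
        lo, hi = self.domain
        tol = tol_frac * max(hi - lo, 1.0)
        return (lo - tol) <= u <= (hi + tol)


@dataclass(frozen=True)
class KeypointTriple:
    """Wheat-organ keypoints: A stem base, B spike tip, C leaf node.

    A leaf angle additionally needs a direction for the leaf itself; ``L``
    (leaf reference, e.g. the leaf bounding-box center or a clicked leaf tip)
    supplies it and is an explicit optional fourth point.
    """

    A: tuple[float, float]
    B: tuple[float, float]
    C: tuple[float, float]
    L: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        pts = [np.asarray(p, dtype=float) for p in (self.A, self.B, self.C)]
        for i in range(3):
            for j in range(i + 1, 3):
                if np.allclose(pts[i], pts[j]):
                    raise DegenerateGeometryError("keypoints A, B, C must be distinct")


def total_least_squares_line(points: np.ndarray) -> LineModel:
    """Orthogonal-distance (total least squares) line through a point set."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise InsufficientDataError("need at least 2 points for a line")
    mean = pts.mean(axis=0)
    centered = pts - mean
    if np.allclose(centered, 0):
        raise DegenerateGeometryError("all points coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return LineModel(point=mean, direction=vt[0], inlier_count=len(pts))


def ransac_major_axis(
    points: np.ndarray,
    iterations: int = 200,
    inlier_tol_px: float = 2.0,
    seed: int = 0,
) -> LineModel:
    """Robust major-axis fit: two-point RANSAC + total-least-squares refit.

    Repeatedly samples two distinct points, counts points within
    ``inlier_tol_px`` orthogonal distance of the hypothesized line, keeps the
    hypothesis with the most inliers, and refits by total least squares on
    that inlier set. Deterministic for a fixed ``seed``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise InsufficientDataError("need an (n >= 2, 2) point array")
    if np.allclose(pts, pts[0]):
        raise DegenerateGeometryError("all points coincide")
    if len(pts) == 2:
        return total_least_squares_line(pts)
    rng = np.random.default_rng(seed)
    best_inliers: np.ndarray | None = None
    best_count = -1
    for _ in range(iterations):
        i, j = rng.choice(len(pts), size=2, replace=False)
        p, q = pts[i], pts[j]
        d = q - p
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        d = d / norm
        rel = pts - p
        dist = np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])
        inliers = dist <= inlier_tol_px
        count = int(inliers.sum())
        if count > best_count:
            best_count = count
            best_inliers = inliers
    if best_inliers is None:  # every sampled pair coincident
        raise DegenerateGeometryError("could not hypothesize a line")
    refit = total_least_squares_line(pts[best_inliers])
    return LineModel(point=refit.point, direction=refit.direction, inlier_count=best_count)


def fit_ear_axis(centers: np.ndarray, degree: int = 3) -> PolyAxis:
    """Fit the ear (rachis) axis through spikelet center points.

    The centers are rotated so their principal direction becomes the
    independent axis, then a degree-``degree`` polynomial is least-squares
    fitted to the transverse coordinate.
    """
    pts = np.asarray(centers, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidParameterError("centers must be an (n, 2) array")
    if degree < 1:
        raise InvalidParameterError("degree must be >= 1")
    if len(pts) < degree + 1:
        raise InsufficientDataError(
            f"need at least {degree + 1} centers for degree {degree}"
        )
    mean = pts.mean(axis=0)
    centered = pts - mean
    if np.allclose(centered, 0):
        raise DegenerateGeometryError("all centers coincide")
    # principal axes: eigenvectors of the 2x2 covariance
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    u_axis = _normalize_direction(vt[0])
    v_axis = np.asarray([-u_axis[1], u_axis[0]])
    rotation = np.column_stack([u_axis, v_axis])
    uv = centered @ rotation
    coeffs = np.polyfit(uv[:, 0], uv[:, 1], deg=degree)
    resid = np.polyval(coeffs, uv[:, 0]) - uv[:, 1]
    return PolyAxis(
        degree=degree,
        coefficients=coeffs,
        domain=(float(uv[:, 0].min()), float(uv[:, 0].max())),
        rotation=rotation,
        mean=mean,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def _zs_neighbors(p: np.ndarray) -> tuple[np.ndarray, ...]:
    """The 8 neighbor planes P2..P9 (N, NE, E, SE, S, SW, W, NW) of a padded
    binary array, each aligned with the unpadded grid."""
    c = p[1:-1, 1:-1]
    n = p[:-2, 1:-1]
    ne = p[:-2, 2:]
    e = p[1:-1, 2:]
    se = p[2:, 2:]
    s = p[2:, 1:-1]
    sw = p[2:, :-2]
    w = p[1:-1, :-2]
    nw = p[:-2, :-2]
    del c
    return n, ne, e, se, s, sw, w, nw


def zhang_suen_thin(mask: np.ndarray) -> np.ndarray:
    """Zhang-Suen thinning: reduce a binary shape to a 1-px-wide skeleton.

    Iterates the two parallel sub-passes until no pixel is deleted. A pixel
    P1 is deleted in a sub-pass when (a) its 8-neighbor count B is in [2, 6],
    (b) the number of 0->1 transitions A around the ordered neighborhood is
    exactly 1, and (c/d) the sub-pass-specific products of compass neighbors
    vanish (P2*P4*P6 = 0 and P4*P6*P8 = 0 in the first sub-pass; P2*P4*P8 = 0
    and P2*P6*P8 = 0 in the second).

    The output is always a subset of the input foreground, and the operation
    is idempotent.
    """
    img = np.asarray(mask).astype(bool)
    changed = True
    while changed:
        changed = False
        for subpass in (0, 1):
            p = np.pad(img, 1).astype(np.uint8)
            n2, n3, n4, n5, n6, n7, n8, n9 = _zs_neighbors(p)
            seq = [n2, n3, n4, n5, n6, n7, n8, n9, n2]
            b = sum(seq[:8])
            a = sum((seq[k] == 0) & (seq[k + 1] == 1) for k in range(8))
            if subpass == 0:
                c1 = n2 * n4 * n6 == 0
                c2 = n4 * n6 * n8 == 0
            else:
                c1 = n2 * n4 * n8 == 0
                c2 = n2 * n6 * n8 == 0
            delete = img & (b >= 2) & (b <= 6) & (a == 1) & c1 & c2
            if delete.any():
                img = img & ~delete
                changed = True
    return img


def angle_at_vertex(vertex, p1, p2) -> float:
    """Angle in degrees at ``vertex`` between rays toward p1 and p2."""
    v = np.asarray(vertex, dtype=float)
    a = np.asarray(p1, dtype=float) - v
    b = np.asarray(p2, dtype=float) - v
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateGeometryError("angle undefined for coincident points")
    cosang = np.clip((a @ b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def flag_leaf_angle(k: KeypointTriple, mode: str = "node_stem_leaf") -> float:
    """Flag-leaf inclination from wheat-organ keypoints.

    ``node_stem_leaf`` (default): angle at the leaf node C between the stem
    direction toward the spike tip (C -> B) and the leaf reference direction
    (C -> L), in [0, 180].

    ``stem_axis_leaf``: angle between the whole stem line A -> B (undirected)
    and the leaf vector C -> L, folded to [0, 90].

    Both modes need the leaf reference point L.
    """
    if k.L is None:
        raise InsufficientDataError("leaf reference point L is required")
    if mode == "node_stem_leaf":
        return angle_at_vertex(k.C, k.B, k.L)
    if mode == "stem_axis_leaf":
        stem = np.asarray(k.B, dtype=float) - np.asarray(k.A, dtype=float)
        leaf = np.asarray(k.L, dtype=float) - np.asarray(k.C, dtype=float)
        ang = angle_at_vertex((0.0, 0.0), stem, leaf)
        return float(min(ang, 180.0 - ang))
    raise InvalidParameterError(f"unknown mode {mode!r}")


def spikelet_angle(
    spikelet_axis: LineModel,
    ear_axis: PolyAxis,
    center,
    domain_tol_frac: float = 0.05,
) -> float:
    """Angle between a spikelet's major axis and the local ear-axis tangent.

    The ear-axis tangent is taken at the axis coordinate nearest to the
    spikelet center; the angle is folded to [0, 90] degrees.
    """
    u = ear_axis.project(np.asarray(center, dtype=float))
    if not ear_axis.in_domain(u, tol_frac=domain_tol_frac):
        raise OutOfDomainError(
            f"center projects to u={u:.1f}, outside domain {ear_axis.domain}"
        )
    lo, hi = ear_axis.domain
    tangent = ear_axis.tangent_at(float(np.clip(u, lo, hi)))
    ang = angle_at_vertex((0.0, 0.0), spikelet_axis.direction, tangent)
    return float(min(ang, 180.0 - ang))
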