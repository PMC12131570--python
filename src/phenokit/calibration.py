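"""Reference-object detection and pixel-to-physical scale calibration.

Top-down phenotyping captures commonly include either a coin of known
diameter (seed trays, tomato scenes) or a white rectangular field marker of
known real-world size (wheat plots). This module detects those references,
derives the scale factor (mm per pixel), and rectifies perspective-distorted
plot images using the marker homography.

Coordinates are (row, col), 0-based, origin top-left. Conversions are linear
in ``mm_per_px`` for lengths, quadratic for areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure, transform

from ._raster import (
    as_rgb8,
    circularity,
    contour_perimeter,
    luminance8,
    polygon_signed_area,
    trace_contour,
)
from .errors import (
    CoinNotFoundError,
    DegenerateGeometryError,
    InvalidParameterError,
    MarkerNotFoundError,
)

__all__ = [
    "CircleDetection",
    "QuadMarker",
    "Calibration",
    "PhysicalValue",
    "RectificationResult",
    "detect_coin",
    "scale_from_coin",
    "detect_rect_marker",
    "rectify_from_marker",
    "convert_units",
    "to_pixels",
]


@dataclass(frozen=True)
class CircleDetection:
    """A circle fitted to a detected contour.

    ``circularity`` is 4*pi*area/perimeter**2 of the underlying contour,
    1.0 for a perfect disc.
    """

    center: tuple[float, float]  # (row, col)
    radius: float  # px
    circularity: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidParameterError("circle radius must be positive")


@dataclass(frozen=True)
class QuadMarker:
    """An ordered quadrilateral marker with known real-world size."""

    corners: np.ndarray  # (4, 2) float, (row, col), counter-clockwise
    area_px: float
    real_width_m: float
    real_height_m: float

    def __post_init__(self) -> None:
        c = np.asarray(self.corners, dtype=float)
        if c.shape != (4, 2):
            raise InvalidParameterError("marker needs exactly 4 corners")
        object.__setattr__(self, "corners", c)
        if self.real_width_m <= 0 or self.real_height_m <= 0:
            raise InvalidParameterError("marker real dimensions must be positive")
        if self.area_px <= 0:
            raise InvalidParameterError("marker pixel area must be positive")


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-physical scale. ``source`` is one of coin/marker/manual/none."""

    mm_per_px: float | None
    source: str = "none"

    _SOURCES = ("coin", "marker", "manual", "none")

    def __post_init__(self) -> None:
        if self.source not in self._SOURCES:
            raise InvalidParameterError(f"unknown calibration source {self.source!r}")
        if self.source != "none" and (self.mm_per_px is None or self.mm_per_px <= 0):
            raise InvalidParameterError("mm_per_px must be positive when calibrated")

    @classmethod
    def none(cls) -> "Calibration":
        return cls(mm_per_px=None, source="none")

    @classmethod
    def manual(cls, mm_per_px: float) -> "Calibration":
        return cls(mm_per_px=mm_per_px, source="manual")

    @property
    def calibrated(self) -> bool:
        return self.source != "none" and self.mm_per_px is not None

    def to_dict(self) -> dict:
        return {"mm_per_px": self.mm_per_px, "source": self.source}


@dataclass(frozen=True)
class PhysicalValue:
    """A measurement with its unit; ``calibrated`` is False for raw pixels."""

    value: float
    unit: str
    calibrated: bool


@dataclass(frozen=True)
class RectificationResult:
    """Output of :func:`rectify_from_marker`."""

    image: np.ndarray
    calibration: Calibration
    transform: transform.ProjectiveTransform
    marker_corners: np.ndarray = field(repr=False)  # rectified (4,2) (row,col)


def detect_coin(
    image: np.ndarray,
    min_radius_px: float = 3.0,
    circularity_min: float = 0.85,
) -> CircleDetection:
    """Find the most circular bright contour and fit a circle to it.

    The luminance channel is binarized with the intensity threshold that
    maximizes between-class variance; each connected component's contour
    circularity (4*pi*A/P**2) is computed, and the most circular component
    with circularity >= ``circularity_min`` and equivalent radius >=
    ``min_radius_px`` wins (ties broken by larger radius).

    Raises
    ------
    CoinNotFoundError
        If no component qualifies. Pipelines then fall back to pixel units.
    """
    from .segmentation import otsu_threshold  # local import: avoid cycle

    if min_radius_px < 3:
        raise InvalidParameterError("min_radius_px must be >= 3")
    lum = luminance8(image)
    hist = np.bincount(lum.ravel(), minlength=256)
    if hist[1:].sum() == 0 and hist[0] == lum.size:
        raise CoinNotFoundError("image is entirely black")
    t = otsu_threshold(hist)
    mask = lum > t
    labels = measure.label(mask, connectivity=2)
    best: CircleDetection | None = None
    for region in measure.regionprops(labels):
        radius = float(np.sqrt(region.area / np.pi))
        if radius < min_radius_px:
            continue
        inst = labels == region.label
        circ = circularity(float(region.area), contour_perimeter(inst))
        if circ < circularity_min:
            continue
        cand = CircleDetection(
            center=(float(region.centroid[0]), float(region.centroid[1])),
            radius=radius,
            circularity=min(circ, 1.0),
        )
        if (
            best is None
            or cand.circularity > best.circularity
            or (cand.circularity == best.circularity and cand.radius > best.radius)
        ):
            best = cand
    if best is None:
        raise CoinNotFoundError(
            f"no contour with circularity >= {circularity_min} "
            f"and radius >= {min_radius_px} px"
        )
    return best


def scale_from_coin(detection: CircleDetection, coin_diameter_mm: float) -> Calibration:
    """Scale factor from a detected coin: mm_per_px = diameter / (2 * radius)."""
    if coin_diameter_mm <= 0:
        raise InvalidParameterError("coin diameter must be positive")
    return Calibration(mm_per_px=coin_diameter_mm / (2.0 * detection.radius), source="coin")


def _quad_from_hull(hull: np.ndarray) -> np.ndarray:
    """Pick 4 hull vertices forming a maximal quadrilateral.

    Takes the farthest vertex pair as a diagonal, then the vertex farthest
    from that diagonal on each side. Adequate for convex quadrilateral blobs.
    """
    d2 = np.sum((hull[:, None, :] - hull[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    p, q = hull[i], hull[j]
    dvec = q - p
    # signed cross product in (x=col, y=row) plane
    cross = dvec[1] * (hull[:, 0] - p[0]) - dvec[0] * (hull[:, 1] - p[1])
    if cross.max() <= 1e-9 or cross.min() >= -1e-9:
        raise MarkerNotFoundError("white region is not quadrilateral")
    r = hull[int(np.argmax(cross))]
    s = hull[int(np.argmin(cross))]
    return np.asarray([p, r, q, s], dtype=float)


def _refine_corners(contour: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Refine corners by fitting a line to each edge's contour points and
    intersecting adjacent lines (sub-pixel corners)."""
    pts = contour[:-1]
    # assign each contour point to its nearest edge segment
    dists = np.empty((4, len(pts)))
    for e in range(4):
        a, b = quad[e], quad[(e + 1) % 4]
        ab = b - a
        tt = np.clip(((pts - a) @ ab) / max(ab @ ab, 1e-12), 0.0, 1.0)
        proj = a + tt[:, None] * ab
        dists[e] = np.hypot(*(pts - proj).T)
    edge_of = np.argmin(dists, axis=0)
    lines = []
    for e in range(4):
        sel = pts[edge_of == e]
        a, b = quad[e], quad[(e + 1) % 4]
        elen = np.hypot(*(b - a))
        # drop points near corners where the contour rounds off
        margin = max(2.0, 0.12 * elen)
        keep = (np.hypot(*(sel - a).T) > margin) & (np.hypot(*(sel - b).T) > margin)
        sel = sel[keep]
        if len(sel) < 2:
            sel = np.vstack([a, b])
        centroid = sel.mean(axis=0)
        _, _, vt = np.linalg.svd(sel - centroid, full_matrices=False)
        lines.append((centroid, vt[0]))
    corners = []
    for e in range(4):
        (c1, d1), (c2, d2) = lines[e - 1], lines[e]
        mat = np.column_stack([d1, -d2])
        if abs(np.linalg.det(mat)) < 1e-9:
            return quad  # nearly parallel; keep coarse corners
        t1, _ = np.linalg.solve(mat, c2 - c1)
        corners.append(c1 + t1 * d1)
    return np.asarray(corners)


def _interior_angles(quad: np.ndarray) -> np.ndarray:
    angles = []
    for i in range(4):
        v1 = quad[(i - 1) % 4] - quad[i]
        v2 = quad[(i + 1) % 4] - quad[i]
        cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return np.asarray(angles)


def detect_rect_marker(
    image: np.ndarray,
    whiteness_threshold: int = 210,
    real_width_m: float = 1.0,
    real_height_m: float = 1.0,
    right_angle_tol_deg: float = 15.0,
    min_area_px: int = 400,
) -> QuadMarker:
    """Detect the white rectangular field marker as an ordered quadrilateral.

    Near-white pixels (all channels >= ``whiteness_threshold``) are extracted,
    the largest connected component kept, and its outer contour reduced to a
    4-corner convex quadrilateral (sub-pixel corners from edge line fits).
    Verification requires convexity and every interior angle within
    ``right_angle_tol_deg`` of 90 degrees.

    Works for both filled rectangles and rectangular frames (outlines), since
    only the outer contour is used.
    """
    rgb = as_rgb8(image)
    near_white = np.min(rgb, axis=-1) >= whiteness_threshold
    if not near_white.any():
        raise MarkerNotFoundError("no near-white region")
    labels = measure.label(near_white, connectivity=2)
    regions = measure.regionprops(labels)
    region = max(regions, key=lambda r: r.area)
    if region.area < min_area_px:
        raise MarkerNotFoundError("near-white region too small to be a marker")
    component = labels == region.label
    contour = trace_contour(component)
    hull_idx = _convex_hull_indices(contour[:-1])
    quad = _quad_from_hull(contour[:-1][hull_idx])
    quad = _refine_corners(contour, quad)
    quad = _order_ccw(quad)
    angles = _interior_angles(quad)
    if np.any(np.abs(angles - 90.0) > right_angle_tol_deg):
        raise MarkerNotFoundError(
            f"quadrilateral angles {np.round(angles, 1)} fail the "
            f"right-angle tolerance of {right_angle_tol_deg} deg"
        )
    closed = np.vstack([quad, quad[:1]])
    area = abs(polygon_signed_area(closed))
    return QuadMarker(
        corners=quad,
        area_px=area,
        real_width_m=real_width_m,
        real_height_m=real_height_m,
    )


def _convex_hull_indices(points: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull

    return ConvexHull(points).vertices


def _order_ccw(quad: np.ndarray) -> np.ndarray:
    """Order corners counter-clockwise (in the x=col, y=row plane), starting
    from the top-left corner (minimal row + col)."""
    center = quad.mean(axis=0)
    ang = np.arctan2(quad[:, 0] - center[0], quad[:, 1] - center[1])
    order = np.argsort(-ang)  # decreasing atan2(row, col) = CCW in (col,row)
    quad = quad[order]
    start = int(np.argmin(quad.sum(axis=1)))
    return np.roll(quad, -start, axis=0)


def rectify_from_marker(image: np.ndarray, marker: QuadMarker) -> RectificationResult:
    """Rectify a perspective-distorted image using the marker homography.

    Computes the projective transform mapping the marker's corners onto an
    axis-aligned rectangle whose pixel aspect matches the marker's real-world
    aspect, warps the full image with it, and returns a marker-based
    calibration (mm_per_px consistent with the rectified marker width).
    """
    corners = marker.corners
    # reject (near-)collinear corner triples
    for i in range(4):
        a, b, c = corners[i], corners[(i + 1) % 4], corners[(i + 2) % 4]
        cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(cross) < 1e-6:
            raise DegenerateGeometryError("marker corners are collinear")
    aspect = marker.real_width_m / marker.real_height_m
    width_px = float(np.sqrt(marker.area_px * aspect))
    height_px = width_px / aspect
    origin = corners.min(axis=0)
    tl = origin
    target = np.asarray(
        [
            tl,
            tl + [height_px, 0],
            tl + [height_px, width_px],
            tl + [0, width_px],
        ]
    )
    # corners are CCW from top-left in (col,row) plane: TL, BL, BR, TR in
    # image terms; match target ordering accordingly.
    src_xy = corners[:, ::-1]
    dst_xy = target[:, ::-1]
    tform = transform.ProjectiveTransform.from_estimate(src_xy, dst_xy)
    if not tform:
        raise DegenerateGeometryError("homography estimation failed")
    rgb = as_rgb8(image)
    warped = transform.warp(
        rgb, inverse_map=tform.inverse, output_shape=rgb.shape[:2], order=1,
        preserve_range=True,
    )
    warped = np.clip(np.rint(warped), 0, 255).astype(np.uint8)
    cal = Calibration(
        mm_per_px=marker.real_width_m * 1000.0 / width_px, source="marker"
    )
    return RectificationResult(
        image=warped, calibration=cal, transform=tform, marker_corners=target
    )


_UNITS = {
    "length": ("mm", "px"),
    "area": ("mm2", "px2"),
    "count_density": ("per_m2", "per_px2"),
}


def convert_units(value_px: float, kind: str, cal: Calibration) -> PhysicalValue:
    """Convert a pixel-domain measurement to physical units.

    length -> mm, area -> mm^2, count_density (per px^2) -> per m^2.
    If ``cal`` carries no scale the pixel value is returned flagged as
    uncalibrated rather than raising.
    """
    if kind not in _UNITS:
        raise InvalidParameterError(f"unknown kind {kind!r}")
    phys_unit, px_unit = _UNITS[kind]
    if not cal.calibrated:
        return PhysicalValue(float(value_px), px_unit, calibrated=False)
    s = cal.mm_per_px
    if kind == "length":
        out = value_px * s
    elif kind == "area":
        out = value_px * s**2
    else:  # count per px^2 -> per m^2; 1 px = s/1000 m
        out = value_px / (s / 1000.0) ** 2
    return PhysicalValue(float(out), phys_unit, calibrated=True)


def to_pixels(value: float, kind: str, cal: Calibration) -> float:
    """Inverse of :func:`convert_units` for calibrated values."""
    if kind not in _UNITS:
        raise InvalidParameterError(f"unknown kind {kind!r}")
    if not cal.calibrated:
        return float(value)
    s = cal.mm_per_px
    if kind == "length":
        return float(value / s)
    if kind == "area":
        return float(value / s**2)
    return float(value * (s / 1000.0) ** 2)
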