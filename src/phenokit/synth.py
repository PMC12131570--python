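"""Synthetic phenotyping scenes with exact machine-readable ground truth.

Each generator emulates one of the recommended capture setups the pipelines
target — seeds or tomatoes on a black background photographed top-down with
a coin for scale, a wheat ear viewed from the side, a maize ear viewed
horizontally, a canopy viewed top-down, a field plot with a white
rectangular marker — and returns ``(image, ground_truth)`` where the ground
truth records the exact generative parameters (centers, sizes, counts,
scale, homography) for use as a test oracle.

Rasterization is purely integer/analytic (a pixel belongs to a shape iff its
center satisfies the shape inequality) with no anti-aliasing, so rendered
masks match the ground truth exactly; generators are pure functions of their
spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "SeedTraySpec",
    "TomatoSceneSpec",
    "SpikeletEarSpec",
    "CornLatticeSpec",
    "CanopySpec",
    "WheatPlotSpec",
    "gen_seed_tray",
    "gen_tomato_scene",
    "gen_spikelet_ear",
    "gen_corn_lattice",
    "gen_canopy",
    "gen_wheat_plot",
    "r_squared",
]


# ----------------------------------------------------------------- drawing

def _background(height: int, width: int, rng: np.random.Generator,
                base: int = 10, noise_sigma: float = 5.0) -> np.ndarray:
    """Near-black background with additive Gaussian noise, 8-bit RGB."""
    img = np.full((height, width, 3), float(base))
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=(height, width, 1))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _ellipse_mask_local(center, a: float, b: float, theta: float,
                        shape) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center rasterization of a rotated ellipse.

    ``theta`` is the major-axis angle in the (x=col, y=row) plane, measured
    from the +col axis (y pointing down). Returns (rows, cols) index arrays.
    """
    cy, cx = center  # (row, col)
    ext = max(a, b) + 1.5
    r0 = max(int(np.floor(cy - ext)), 0)
    r1 = min(int(np.ceil(cy + ext)) + 1, shape[0])
    c0 = max(int(np.floor(cx - ext)), 0)
    c1 = min(int(np.ceil(cx + ext)) + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dx = cc - cx
    dy = rr - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    inside = u * u + v * v <= 1.0
    return rr[inside], cc[inside]


def _draw_ellipse(img: np.ndarray, center, a: float, b: float, theta: float,
                  color) -> int:
    rr, cc = _ellipse_mask_local(center, a, b, theta, img.shape[:2])
    img[rr, cc] = color
    return len(rr)


def _draw_disc(img: np.ndarray, center, radius: float, color) -> int:
    return _draw_ellipse(img, center, radius, radius, 0.0, color)


def _polygon_mask(corners_rc: np.ndarray, shape) -> np.ndarray:
    from skimage.draw import polygon

    rr, cc = polygon(corners_rc[:, 0], corners_rc[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _hsv_to_rgb8(h_deg: float, s: float, v: float) -> np.ndarray:
    """Single HSV color (hue in degrees) to an 8-bit RGB triple."""
    h = (h_deg % 360.0) / 60.0
    i = int(h) % 6
    f = h - int(h)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.clip(np.rint(np.asarray(rgb) * 255), 0, 255).astype(np.uint8)


def _ellipse_radius_along(a: float, b: float, psi: float) -> float:
    """Boundary radius of an (a, b) ellipse along direction ``psi`` from its
    major axis."""
    return a * b / np.hypot(b * np.cos(psi), a * np.sin(psi))


def _shapely_ellipse(cx: float, cy: float, a: float, b: float, theta: float):
    from shapely import affinity
    from shapely.geometry import Point

    e = Point(0.0, 0.0).buffer(1.0, quad_segs=48)
    e = affinity.scale(e, a, b)
    e = affinity.rotate(e, np.degrees(theta), origin=(0, 0))
    return affinity.translate(e, cx, cy)


def _tangent_distance(a1, b1, t1, a2, b2, t2, phi) -> float:
    """Center distance at which two oriented ellipses just touch when the
    second is displaced from the first along direction ``phi``.

    Found by bisection on the displacement; unlike the sum of boundary radii
    along the center line, this accounts for the full shapes (tilted ellipses
    can cross far from the center line).
    """
    e1 = _shapely_ellipse(0.0, 0.0, a1, b1, t1)
    ux, uy = np.cos(phi), np.sin(phi)
    lo, hi = 0.0, 2.0 * (max(a1, b1) + max(a2, b2))
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        e2 = _shapely_ellipse(mid * ux, mid * uy, a2, b2, t2)
        if e1.intersects(e2):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ------------------------------------------------------------- seed trays

@dataclass(frozen=True)
class SeedTraySpec:
    """Top-down seed tray: ellipse seeds on black, optional coin for scale."""

    n_seeds: int = 50
    height: int = 700
    width: int = 1000
    semi_major_range: tuple[float, float] = (12.0, 22.0)
    aspect_range: tuple[float, float] = (1.4, 2.2)
    n_touching_pairs: int = 0
    overlap: float = 0.3  # 1 - center distance / sum of touching radii
    include_coin: bool = True
    coin_radius_px: float = 100.0
    coin_diameter_mm: float = 25.0
    noise_sigma: float = 5.0
    min_gap_px: float = 4.0
    seed: int = 0


def _place_disjoint(rng, n, bounds, radii, existing, min_gap):
    """Rejection-sample n centers with pairwise bounding-circle separation."""
    (rlo, rhi), (clo, chi) = bounds
    centers = []
    placed = list(existing)
    for i in range(n):
        for _ in range(4000):
            cy = rng.uniform(rlo + radii[i], rhi - radii[i])
            cx = rng.uniform(clo + radii[i], chi - radii[i])
            ok = all(
                np.hypot(cy - py, cx - px) >= radii[i] + pr + min_gap
                for py, px, pr in placed
            )
            if ok:
                centers.append((cy, cx))
                placed.append((cy, cx, radii[i]))
                break
        else:
            raise InvalidParameterError(
                "could not place all instances; scene too crowded"
            )
    return centers


def gen_seed_tray(spec: SeedTraySpec) -> tuple[np.ndarray, dict]:
    rng = np.random.default_rng(spec.seed)
    img = _background(spec.height, spec.width, rng, noise_sigma=spec.noise_sigma)
    gt: dict = {"kind": "seed_tray", "count": spec.n_seeds}
    existing = []
    if spec.include_coin:
        ccy = rng.uniform(spec.coin_radius_px + 20, spec.height - spec.coin_radius_px - 20)
        ccx = rng.uniform(spec.coin_radius_px + 20, spec.coin_radius_px + 60)
        _draw_disc(img, (ccy, ccx), spec.coin_radius_px, (168, 168, 168))
        existing.append((ccy, ccx, spec.coin_radius_px))
        gt["coin"] = {
            "center": [ccy, ccx],
            "radius_px": spec.coin_radius_px,
            "diameter_mm": spec.coin_diameter_mm,
        }
        gt["mm_per_px"] = spec.coin_diameter_mm / (2 * spec.coin_radius_px)
    else:
        gt["coin"] = None
        gt["mm_per_px"] = None

    n = spec.n_seeds
    n_pairs = spec.n_touching_pairs
    if 2 * n_pairs > n:
        raise InvalidParameterError("more touching pairs than seeds")
    a = rng.uniform(*spec.semi_major_range, size=n)
    aspect = rng.uniform(*spec.aspect_range, size=n)
    b = a / aspect
    theta = rng.uniform(0, np.pi, size=n)
    n_single = n - 2 * n_pairs
    # singles and pair anchors placed with disjoint bounding circles; a pair
    # anchor reserves extra room for its touching partner
    anchor_idx = list(range(n_single + n_pairs))
    pair_partner_idx = list(range(n_single + n_pairs, n))
    bounds = ((10, spec.height - 10), (10, spec.width - 10))
    anchor_margin = []
    for i in anchor_idx:
        m = a[i]
        if i >= n_single:
            m += 2 * a[pair_partner_idx[i - n_single]]
        anchor_margin.append(m)
    centers_anchor = _place_disjoint(
        rng, len(anchor_idx), bounds, anchor_margin, existing, spec.min_gap_px
    )
    centers = [None] * n
    for i, c in zip(anchor_idx, centers_anchor):
        centers[i] = c
    # partners placed touching their anchors; per-pair overlap drawn up to
    # spec.overlap and interpreted as penetration depth relative to the
    # smaller minor semi-axis, measured from the true tangency distance so
    # fusion depth is controlled regardless of the ellipses' tilts
    for k, j in enumerate(pair_partner_idx):
        i = n_single + k  # anchor index
        cy, cx = centers[i]
        phi = rng.uniform(0, 2 * np.pi)
        o = rng.uniform(min(0.05, spec.overlap), spec.overlap)
        d_t = _tangent_distance(a[i], b[i], theta[i], a[j], b[j], theta[j], phi)
        # floor keeps the rasterized pair 8-connected
        d = d_t - max(1.5, o * min(b[i], b[j]))
        centers[j] = (cy + d * np.sin(phi), cx + d * np.cos(phi))
    base = np.asarray([150.0, 112.0, 72.0])
    areas = []
    for i in range(n):
        color = np.clip(base + rng.uniform(-25, 25, size=3), 0, 255).astype(np.uint8)
        areas.append(_draw_ellipse(img, centers[i], a[i], b[i], theta[i], color))
    gt.update(
        centers=[[float(cy), float(cx)] for cy, cx in centers],
        semi_major=a.tolist(),
        semi_minor=b.tolist(),
        orientations=theta.tolist(),
        areas_px=areas,
        n_touching_pairs=n_pairs,
        expected_components=n - n_pairs,
        mean_length_px=float(np.mean(2 * a)) if n else 0.0,
        mean_width_px=float(np.mean(2 * b)) if n else 0.0,
    )
    return img, gt


# ---------------------------------------------------------------- tomatoes

@dataclass(frozen=True)
class TomatoSceneSpec:
    """Top-down tomatoes (red discs, hue-jittered) with a grey coin."""

    n_tomatoes: int = 12
    height: int = 700
    width: int = 1000
    radius_range: tuple[float, float] = (40.0, 80.0)
    hue_jitter_deg: float = 10.0
    include_coin: bool = True
    coin_radius_px: float = 90.0
    coin_diameter_mm: float = 25.0
    noise_sigma: float = 5.0
    min_gap_px: float = 6.0
    tangent_pairs: int = 0  # pairs rendered exactly tangent (distance = r1+r2)
    seed: int = 0


def gen_tomato_scene(spec: TomatoSceneSpec) -> tuple[np.ndarray, dict]:
    rng = np.random.default_rng(spec.seed)
    img = _background(spec.height, spec.width, rng, noise_sigma=spec.noise_sigma)
    gt: dict = {"kind": "tomato", "count": spec.n_tomatoes}
    existing = []
    if spec.include_coin:
        ccy = rng.uniform(spec.coin_radius_px + 20, spec.height - spec.coin_radius_px - 20)
        ccx = rng.uniform(spec.coin_radius_px + 20, spec.coin_radius_px + 60)
        _draw_disc(img, (ccy, ccx), spec.coin_radius_px, (158, 158, 158))
        existing.append((ccy, ccx, spec.coin_radius_px))
        gt["coin"] = {"center": [ccy, ccx], "radius_px": spec.coin_radius_px,
                      "diameter_mm": spec.coin_diameter_mm}
        gt["mm_per_px"] = spec.coin_diameter_mm / (2 * spec.coin_radius_px)
    else:
        gt["coin"] = None
        gt["mm_per_px"] = None
    n = spec.n_tomatoes
    n_pairs = spec.tangent_pairs
    if 2 * n_pairs > n:
        raise InvalidParameterError("more tangent pairs than tomatoes")
    radii = rng.uniform(*spec.radius_range, size=n)
    n_single = n - 2 * n_pairs
    anchors = list(range(n_single + n_pairs))
    partners = list(range(n_single + n_pairs, n))
    margins = []
    for i in anchors:
        m = radii[i]
        if i >= n_single:
            m += 2 * radii[partners[i - n_single]]
        margins.append(m)
    bounds = ((10, spec.height - 10), (10, spec.width - 10))
    centers = [None] * n
    for i, c in zip(anchors, _place_disjoint(rng, len(anchors), bounds, margins,
                                             existing, spec.min_gap_px)):
        centers[i] = c
    for k, j in enumerate(partners):
        i = n_single + k
        cy, cx = centers[i]
        phi = rng.uniform(0, 2 * np.pi)
        d = radii[i] + radii[j]  # exactly tangent
        centers[j] = (cy + d * np.sin(phi), cx + d * np.cos(phi))
    hues = rng.uniform(-spec.hue_jitter_deg, spec.hue_jitter_deg, size=n) % 360.0
    for i in range(n):
        color = _hsv_to_rgb8(hues[i], 0.85, 0.85)
        _draw_disc(img, centers[i], radii[i], color)
    gt.update(
        centers=[[float(cy), float(cx)] for cy, cx in centers],
        radii=radii.tolist(),
        hues_deg=hues.tolist(),
        tangent_pairs=n_pairs,
        mean_diameter_px=float(np.mean(2 * radii)) if n else 0.0,
    )
    return img, gt


# ---------------------------------------------------------- spikelet ears

@dataclass(frozen=True)
class SpikeletEarSpec:
    """Side view of a wheat ear: spikelet ellipses placed alternately along a
    polynomial (default cubic) rachis axis at a fixed angle to its tangent."""

    n_spikelets: int = 18
    height: int = 900
    width: int = 620
    semi_major: float = 26.0
    semi_minor: float = 10.0
    angle_to_tangent_deg: float = 35.0
    lateral_offset_px: float = 8.0
    curvature: float = 1.0  # scales the random cubic coefficients
    center_jitter_px: float = 0.0
    size_jitter_frac: float = 0.08
    noise_sigma: float = 5.0
    seed: int = 0


def _ear_axis_fn(spec: SpikeletEarSpec, rng: np.random.Generator):
    """Random mild cubic x = f(y), returned with its derivative."""
    y0 = spec.height / 2.0
    c1 = rng.uniform(-0.12, 0.12) * spec.curvature
    c2 = rng.uniform(-2.5e-4, 2.5e-4) * spec.curvature
    c3 = rng.uniform(-8e-7, 8e-7) * spec.curvature
    cx = spec.width / 2.0

    def f(y):
        t = y - y0
        return cx + c1 * t + c2 * t**2 + c3 * t**3

    def df(y):
        t = y - y0
        return c1 + 2 * c2 * t + 3 * c3 * t**2

    return f, df, (cx, y0, c1, c2, c3)


def gen_spikelet_ear(spec: SpikeletEarSpec) -> tuple[np.ndarray, dict]:
    rng = np.random.default_rng(spec.seed)
    img = _background(spec.height, spec.width, rng, noise_sigma=spec.noise_sigma)
    f, df, coeffs = _ear_axis_fn(spec, rng)
    n = spec.n_spikelets
    margin = 70.0
    ys = np.linspace(margin, spec.height - margin, n) if n > 1 else np.asarray(
        [spec.height / 2.0]
    )
    centers = []
    thetas = []
    sizes = []
    color_base = np.asarray([196.0, 182.0, 120.0])
    for i, y in enumerate(ys):
        x = f(y)
        # tangent direction in (x, y): (df, 1); its angle from the +x axis
        tangent_ang = np.arctan2(1.0, df(y))
        sgn = 1.0 if i % 2 == 0 else -1.0
        theta = tangent_ang + sgn * np.radians(spec.angle_to_tangent_deg)
        # normal (unit, in (x, y))
        nx, ny = -np.sin(tangent_ang), np.cos(tangent_ang)
        cxp = x + (-sgn) * spec.lateral_offset_px * nx
        cyp = y + (-sgn) * spec.lateral_offset_px * ny
        if spec.center_jitter_px > 0:
            cxp += rng.normal(0, spec.center_jitter_px)
            cyp += rng.normal(0, spec.center_jitter_px)
        jit = 1.0 + rng.uniform(-spec.size_jitter_frac, spec.size_jitter_frac)
        a_i, b_i = spec.semi_major * jit, spec.semi_minor * jit
        color = np.clip(color_base + rng.uniform(-18, 18, 3), 0, 255).astype(np.uint8)
        _draw_ellipse(img, (cyp, cxp), a_i, b_i, theta, color)
        centers.append([float(cyp), float(cxp)])
        thetas.append(float(theta))
        sizes.append([float(a_i), float(b_i)])
    gt = {
        "kind": "spikelet_ear",
        "count": n,
        "centers": centers,  # (row, col)
        "orientations": thetas,  # major-axis angle in (x=col, y=row) plane
        "semi_axes": sizes,
        "angle_to_tangent_deg": spec.angle_to_tangent_deg,
        "axis": {"cx": coeffs[0], "y0": coeffs[1], "c1": coeffs[2],
                 "c2": coeffs[3], "c3": coeffs[4]},
        "axis_points": [[float(y), float(f(y))] for y in ys],  # (row, col) on axis
        "tangent_angles": [float(np.arctan2(1.0, df(y))) for y in ys],
    }
    return img, gt


# --------------------------------------------------------- corn lattices

@dataclass(frozen=True)
class CornLatticeSpec:
    """Horizontal view of a maize ear face: a rows x cols kernel lattice."""

    rows: int = 14
    cols: int = 30
    row_pitch: float = 20.0  # cross-axis spacing (between rows)
    col_pitch: float = 26.0  # along-ear spacing (within a row)
    jitter_frac: float = 0.10  # sigma as a fraction of row_pitch
    rotation_deg: float | None = None  # None: random in [0, 180)
    render: bool = False
    kernel_radius: float = 7.0
    noise_sigma: float = 5.0
    seed: int = 0


def gen_corn_lattice(spec: CornLatticeSpec) -> tuple[np.ndarray | None, dict]:
    """Returns (image or None, ground truth). GT points are (x, y)."""
    rng = np.random.default_rng(spec.seed)
    rot = (rng.uniform(0.0, 180.0) if spec.rotation_deg is None
           else float(spec.rotation_deg))
    gx, gy = np.meshgrid(
        np.arange(spec.cols) * spec.col_pitch,
        np.arange(spec.rows) * spec.row_pitch,
    )
    pts = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    row_labels = np.repeat(np.arange(spec.rows), spec.cols)
    sigma = spec.jitter_frac * spec.row_pitch
    if sigma > 0:
        pts += rng.normal(0.0, sigma, size=pts.shape)
    pts -= pts.mean(axis=0)
    th = np.radians(rot)
    rot_mat = np.asarray([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    pts = pts @ rot_mat.T
    gt = {
        "kind": "corn_lattice",
        "rows": spec.rows,
        "cols": spec.cols,
        "count": spec.rows * spec.cols,
        "rotation_deg": rot,
        "points": pts.tolist(),  # (x, y)
        "row_labels": row_labels.tolist(),
        "kernels_per_row": [spec.cols] * spec.rows,
    }
    img = None
    if spec.render:
        pad = 3 * spec.kernel_radius
        mn = pts.min(axis=0) - pad
        shifted = pts - mn
        width = int(np.ceil(shifted[:, 0].max() + pad))
        height = int(np.ceil(shifted[:, 1].max() + pad))
        img = _background(height, width, rng, noise_sigma=spec.noise_sigma)
        for k, (x, y) in enumerate(shifted):
            color = _hsv_to_rgb8(48.0 + rng.uniform(-6, 6), 0.85, 0.9)
            _draw_disc(img, (y, x), spec.kernel_radius, color)
        gt["points_image_xy"] = shifted.tolist()
    return img, gt


# ---------------------------------------------------------------- canopy

@dataclass(frozen=True)
class CanopySpec:
    """Top-down canopy silhouette textured green/brown at an exact fraction."""

    shape: str = "disc"  # disc | star | blob
    radius: float = 200.0
    height: int = 600
    width: int = 600
    green_fraction: float = 0.7
    star_lobes: int = 7
    star_amp: float = 0.35
    noise_sigma: float = 5.0
    seed: int = 0


def _canopy_mask(spec: CanopySpec, rng: np.random.Generator) -> np.ndarray:
    cy, cx = spec.height / 2.0, spec.width / 2.0
    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width]
    dy, dx = rr - cy, cc - cx
    rho = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)
    if spec.shape == "disc":
        rmax = np.full_like(phi, spec.radius)
    elif spec.shape == "star":
        rmax = spec.radius * (1.0 + spec.star_amp * np.cos(spec.star_lobes * phi))
    elif spec.shape == "blob":
        amps = rng.uniform(0.05, 0.18, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        rmax = spec.radius * (
            1.0
            + sum(a * np.cos((k + 2) * phi + p) for k, (a, p) in enumerate(zip(amps, phases)))
        )
    else:
        raise InvalidParameterError(f"unknown canopy shape {spec.shape!r}")
    return rho <= rmax


def gen_canopy(spec: CanopySpec) -> tuple[np.ndarray, dict]:
    if not 0.0 <= spec.green_fraction <= 1.0:
        raise InvalidParameterError("green_fraction must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    img = _background(spec.height, spec.width, rng, noise_sigma=spec.noise_sigma)
    mask = _canopy_mask(spec, rng)
    idx = np.argwhere(mask)
    area = len(idx)
    n_green = int(round(spec.green_fraction * area))
    perm = rng.permutation(area)
    green_idx = idx[perm[:n_green]]
    brown_idx = idx[perm[n_green:]]
    # colors jittered but kept strictly inside / outside the default green band
    if len(green_idx):
        h = rng.uniform(85, 150, size=len(green_idx))
        s = rng.uniform(0.35, 0.85, size=len(green_idx))
        v = rng.uniform(0.35, 0.75, size=len(green_idx))
        img[green_idx[:, 0], green_idx[:, 1]] = np.stack(
            [_hsv_to_rgb8(hh, ss, vv) for hh, ss, vv in zip(h, s, v)]
        )
    if len(brown_idx):
        h = rng.uniform(18, 38, size=len(brown_idx))
        s = rng.uniform(0.45, 0.70, size=len(brown_idx))
        v = rng.uniform(0.35, 0.60, size=len(brown_idx))
        img[brown_idx[:, 0], brown_idx[:, 1]] = np.stack(
            [_hsv_to_rgb8(hh, ss, vv) for hh, ss, vv in zip(h, s, v)]
        )
    gt = {
        "kind": "canopy",
        "shape": spec.shape,
        "area_px": int(area),
        "green_fraction": (n_green / area) if area else 0.0,
        "radius": spec.radius,
        "equivalent_diameter_px": 2.0 * float(np.sqrt(area / np.pi)),
    }
    return img, gt


# ------------------------------------------------------------ wheat plots

@dataclass(frozen=True)
class WheatPlotSpec:
    """Field plot: white rectangular marker frame under a known projective
    warp, bright head-like blobs at a set density inside the marker."""

    height: int = 820
    width: int = 1000
    marker_real_w_m: float = 1.0
    marker_real_h_m: float = 1.0
    marker_px_w: float = 580.0  # outer frame width in the marker plane
    frame_px: float = 12.0
    density_per_m2: float = 60.0
    n_outside: int = 5
    head_semi_axes: tuple[float, float] = (11.0, 6.0)
    warp_px: float = 18.0  # corner perturbation magnitude
    noise_sigma: float = 5.0
    seed: int = 0


def _homography_from_corners(src_xy: np.ndarray, dst_xy: np.ndarray) -> np.ndarray:
    """Exact 3x3 projective matrix mapping 4 source points to 4 targets."""
    rows = []
    for (x, y), (u, v) in zip(src_xy, dst_xy):
        rows.append([x, y, 1, 0, 0, 0, -u * x, -u * y, -u])
        rows.append([0, 0, 0, x, y, 1, -v * x, -v * y, -v])
    _, _, vt = np.linalg.svd(np.asarray(rows, dtype=float))
    h = vt[-1].reshape(3, 3)
    return h / h[2, 2]


def _apply_h(h: np.ndarray, pts_xy: np.ndarray) -> np.ndarray:
    p = np.column_stack([pts_xy, np.ones(len(pts_xy))]) @ h.T
    return p[:, :2] / p[:, 2:3]


def gen_wheat_plot(spec: WheatPlotSpec) -> tuple[np.ndarray, dict]:
    rng = np.random.default_rng(spec.seed)
    img = _background(spec.height, spec.width, rng, noise_sigma=spec.noise_sigma)
    # the marker's real-world size refers to the outer extent of the white
    # frame (what marker detection traces); heads live strictly inside it
    w_out = spec.marker_px_w
    h_out = w_out * spec.marker_real_h_m / spec.marker_real_w_m
    fw = spec.frame_px
    outer_plane = np.asarray([[0, 0], [w_out, 0], [w_out, h_out], [0, h_out]], float)
    inner_plane = outer_plane + np.asarray([[fw, fw], [-fw, fw], [-fw, -fw], [fw, -fw]])
    # destination: centered, mildly perspective-perturbed corner positions
    ox = (spec.width - w_out) / 2.0
    oy = (spec.height - h_out) / 2.0
    base = outer_plane + [ox, oy]
    perturb = rng.uniform(-spec.warp_px, spec.warp_px, size=(4, 2))
    h_mat = _homography_from_corners(outer_plane, base + perturb)
    outer_img = _apply_h(h_mat, outer_plane)
    inner_img = _apply_h(h_mat, inner_plane)
    # frame = filled outer quad minus filled inner quad
    outer_mask = _polygon_mask(outer_img[:, ::-1], img.shape[:2])
    inner_mask = _polygon_mask(inner_img[:, ::-1], img.shape[:2])
    img[outer_mask & ~inner_mask] = (250, 250, 250)
    # heads inside the marker, sampled in the marker plane
    area_m2 = spec.marker_real_w_m * spec.marker_real_h_m
    n_in = int(round(spec.density_per_m2 * area_m2))
    a, b = spec.head_semi_axes
    margin = fw + 2.5 * a
    # sequential dart-throwing placement with pairwise separation so heads
    # stay countable: worst-case reach of two tip-to-tip ellipses is 2a,
    # plus margin for the perspective shrink and interpolation blur the
    # later rectification introduces
    min_sep = 2.9 * a
    placed: list[np.ndarray] = []
    for _ in range(n_in):
        for _ in range(20000):
            cand = np.asarray([
                rng.uniform(margin, w_out - margin),
                rng.uniform(margin, h_out - margin),
            ])
            if all(np.hypot(*(cand - p)) >= min_sep for p in placed):
                placed.append(cand)
                break
        else:
            raise InvalidParameterError("head density too high for the marker area")
    heads_plane = np.asarray(placed).reshape(-1, 2)
    heads_img = _apply_h(h_mat, heads_plane)
    for x, y in heads_img:
        theta = rng.uniform(0, np.pi)
        _draw_ellipse(img, (y, x), a, b, theta, (186, 186, 186))
    # distractor heads outside the marker
    from shapely.geometry import Point, Polygon

    keepout = Polygon(outer_img).buffer(3 * a)
    outside = []
    for _ in range(spec.n_outside):
        for _ in range(500):
            x = rng.uniform(2 * a, spec.width - 2 * a)
            y = rng.uniform(2 * a, spec.height - 2 * a)
            if not keepout.contains(Point(x, y)):
                outside.append((x, y))
                _draw_ellipse(img, (y, x), a, b, rng.uniform(0, np.pi), (186, 186, 186))
                break
    gt = {
        "kind": "wheat_plot",
        "homography": h_mat.tolist(),  # marker plane (x, y) -> image (x, y)
        "inner_corners_image_xy": inner_img.tolist(),
        "outer_corners_image_xy": outer_img.tolist(),
        "inside_count": n_in,
        "outside_count": len(outside),
        "density_per_m2": n_in / area_m2,
        "marker_real_w_m": spec.marker_real_w_m,
        "marker_real_h_m": spec.marker_real_h_m,
        "mm_per_px_plane": spec.marker_real_w_m * 1000.0 / w_out,
        "heads_plane_xy": heads_plane.tolist(),
        "heads_image_xy": heads_img.tolist(),
    }
    return img, gt


# ------------------------------------------------------------- evaluation

def r_squared(predicted, reference) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    The soundness metric used to compare pipeline predictions against scene
    ground truth (and, in field use, against manual measurements).
    """
    pred = np.asarray(predicted, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1 or len(pred) < 2:
        raise InvalidParameterError("need equal-length 1-D inputs with n >= 2")
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0:
        raise InvalidParameterError("reference variance is zero; R^2 undefined")
    ss_res = float(np.sum((pred - ref) ** 2))
    return 1.0 - ss_res / ss_tot
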