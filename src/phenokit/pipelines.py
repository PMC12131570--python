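"""The seven trait pipelines behind one uniform run interface.

Each ``run_*`` function takes an RGB image (or, where detections may come
from an external detector, a point/keypoint set or CSV path) plus a
:class:`PipelineConfig`, and returns a :class:`PipelineResult` holding the
calibration used, the extracted traits, per-instance records where
applicable, and a provenance block (config hash, seed, backend, package
version) that makes the run reproducible. Results serialize to JSON
byte-identically across repeated runs on the same input.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import __version__
from ._raster import as_rgb8, luminance8
from .backends import DetectionBackend, OtsuMaskBackend
from .calibration import (
    Calibration,
    detect_coin,
    detect_rect_marker,
    rectify_from_marker,
    scale_from_coin,
)
from .errors import InvalidParameterError, PhenoKitError
from .geometry import (
    KeypointTriple,
    fit_ear_axis,
    flag_leaf_angle,
    ransac_major_axis,
    spikelet_angle,
    zhang_suen_thin,
)
from .morphometry import green_ratio, measure_instance, summarize_scene
from .row_features import cluster_rows, extract_row_features, pca_align
from .segmentation import (
    HSVBounds,
    LabelMap,
    clean_mask,
    hsv_in_range,
    label_instances,
    otsu_binarize,
    otsu_effectiveness,
    otsu_threshold,
    split_adhesions,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_seed_pheno",
    "run_tomato_pheno",
    "run_spikelet_pheno",
    "run_canopy_pheno",
    "run_corn_pheno",
    "run_leaf_angle",
    "run_wheat_head",
    "PIPELINES",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration shared by all pipelines (YAML-loadable).

    Only the fields a given pipeline uses matter to it; the whole block is
    hashed into provenance so a result can always be traced to its exact
    configuration.
    """

    # calibration
    coin_diameter_mm: float = 25.0
    coin_min_radius_px: float = 40.0
    coin_max_saturation: float = 0.30
    circularity_min: float = 0.85
    marker_width_m: float = 1.0
    marker_height_m: float = 1.0
    whiteness_threshold: int = 210
    right_angle_tol_deg: float = 15.0
    use_calibration: bool = True
    # segmentation
    connectivity: int = 8
    solidity_threshold: float = 0.97
    peak_min_distance: int = 6
    neck_ratio: float = 0.9
    min_area_px: int = 40
    opening_radius: int = 1
    invert: bool = False
    hsv_lower: tuple = (340.0, 0.35, 0.20)  # red band (wraps through 0 deg)
    hsv_upper: tuple = (20.0, 1.0, 1.0)
    green_lower: tuple = (60.0, 0.15, 0.10)
    green_upper: tuple = (180.0, 1.0, 1.0)
    kernel_hsv_lower: tuple = (30.0, 0.40, 0.40)  # yellow maize kernels
    kernel_hsv_upper: tuple = (70.0, 1.0, 1.0)
    # geometry
    ransac_iterations: int = 200
    ransac_tol_px: float = 2.0
    ear_axis_degree: int = 3
    leaf_angle_mode: str = "node_stem_leaf"
    # corn rows
    k_min: int = 4
    k_max: int = 24
    row_multiplier: float | None = None  # whole-ear extrapolation, opt-in
    # wheat heads / yield
    head_min_area_px: int = 30
    head_bimodality_min: float = 0.75  # reject noise-only marker interiors
    grain_weight_g_per_head: float | None = None  # yield needs explicit value
    # determinism
    seed: int = 0

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha1(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        data = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
        return cls(**data)


@dataclass
class PipelineResult:
    """Uniform pipeline output: calibration, traits, provenance, records."""

    pipeline: str
    calibration: Calibration
    traits: dict
    provenance: dict
    records: list = field(default_factory=list)
    labelmap: LabelMap | None = field(default=None, repr=False)
    artifacts: dict = field(default_factory=dict, repr=False)  # not serialized

    def to_dict(self) -> dict:
        return {
            "pipeline": self.pipeline,
            "calibration": self.calibration.to_dict(),
            "traits": _jsonable(self.traits),
            "records": [r.to_dict() for r in self.records],
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=indent)

    def records_frame(self):
        import pandas as pd

        return pd.DataFrame([r.to_dict() for r in self.records])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _provenance(cfg: PipelineConfig, backend: str) -> dict:
    return {
        "version": __version__,
        "config_sha1": cfg.sha1(),
        "seed": cfg.seed,
        "backend": backend,
        "length_width_convention": "min_area_rotated_rect",
    }


# ------------------------------------------------------------ calibration

def _grey_only(image: np.ndarray, max_saturation: float) -> np.ndarray:
    """Black out saturated pixels so only grey (metallic) objects remain."""
    from skimage import color

    rgb = as_rgb8(image)
    sat = color.rgb2hsv(rgb)[..., 1]
    out = rgb.copy()
    out[sat > max_saturation] = 0
    return out


def _coin_calibration(image, cfg: PipelineConfig):
    """(Calibration, CircleDetection | None); falls back to pixel units."""
    if not cfg.use_calibration:
        return Calibration.none(), None
    try:
        det = detect_coin(
            _grey_only(image, cfg.coin_max_saturation),
            min_radius_px=cfg.coin_min_radius_px,
            circularity_min=cfg.circularity_min,
        )
        return scale_from_coin(det, cfg.coin_diameter_mm), det
    except PhenoKitError:
        return Calibration.none(), None


def _exclude_coin(mask: np.ndarray, det) -> np.ndarray:
    """Remove the coin (radius + 2 px dilation) from a trait mask."""
    if det is None:
        return mask
    rr, cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    dist2 = (rr - det.center[0]) ** 2 + (cc - det.center[1]) ** 2
    out = mask.copy()
    out[dist2 <= (det.radius + 2.0) ** 2] = False
    return out


def _measure_all(lm: LabelMap, cal: Calibration):
    return [measure_instance(lm, lab, cal) for lab in range(1, lm.n_instances + 1)]


# --------------------------------------------------------------- pipelines

def run_seed_pheno(image, config: PipelineConfig | None = None) -> PipelineResult:
    """Seed tray analysis: coin scale, thresholding, adhesion splitting,
    per-seed morphometrics (count, length, width, perimeter, area, aspect
    ratio) in pixels and, when the coin is found, millimetres."""
    cfg = config or PipelineConfig()
    img = as_rgb8(image)
    cal, det = _coin_calibration(img, cfg)
    mask = otsu_binarize(img, invert=cfg.invert)
    mask = _exclude_coin(mask, det)
    mask = clean_mask(mask, cfg.min_area_px, cfg.opening_radius)
    lm = label_instances(mask, cfg.connectivity)
    lm = split_adhesions(lm, cfg.solidity_threshold, cfg.peak_min_distance, cfg.neck_ratio)
    records = _measure_all(lm, cal)
    summary = summarize_scene(records, cal)
    return PipelineResult(
        pipeline="seed",
        calibration=cal,
        traits=summary.to_dict(),
        provenance=_provenance(cfg, "otsu"),
        records=records,
        labelmap=lm,
    )


def run_tomato_pheno(image, config: PipelineConfig | None = None) -> PipelineResult:
    """Tomato analysis: wrapped-hue HSV segmentation, instance labeling and
    splitting, per-fruit width/diameter/perimeter/area; grey-coin contour
    check for the scale factor."""
    cfg = config or PipelineConfig()
    img = as_rgb8(image)
    cal, det = _coin_calibration(img, cfg)
    bounds = HSVBounds(cfg.hsv_lower, cfg.hsv_upper)
    mask = hsv_in_range(img, bounds)
    mask = _exclude_coin(mask, det)
    mask = clean_mask(mask, cfg.min_area_px, cfg.opening_radius)
    lm = label_instances(mask, cfg.connectivity)
    lm = split_adhesions(lm, cfg.solidity_threshold, cfg.peak_min_distance, cfg.neck_ratio)
    records = _measure_all(lm, cal)
    summary = summarize_scene(records, cal)
    return PipelineResult(
        pipeline="tomato",
        calibration=cal,
        traits=summary.to_dict(),
        provenance=_provenance(cfg, "hsv"),
        records=records,
        labelmap=lm,
    )


def run_spikelet_pheno(
    image,
    config: PipelineConfig | None = None,
    backend: DetectionBackend | None = None,
) -> PipelineResult:
    """Wheat-ear analysis: segmentation, watershed adhesion splitting,
    per-spikelet RANSAC major axes, polynomial rachis axis through the
    spikelet midpoints, skeleton of the spikelet distribution, and
    spikelet-to-axis angles."""
    cfg = config or PipelineConfig()
    img = as_rgb8(image)
    backend = backend or OtsuMaskBackend(invert=cfg.invert)
    mask = clean_mask(backend.detect(img), cfg.min_area_px, cfg.opening_radius)
    lm = label_instances(mask, cfg.connectivity)
    lm = split_adhesions(lm, cfg.solidity_threshold, cfg.peak_min_distance, cfg.neck_ratio)
    cal = Calibration.none()
    records = _measure_all(lm, cal)
    rng = np.random.default_rng(cfg.seed)
    axes = []
    centers = []
    for lab in range(1, lm.n_instances + 1):
        pts = np.argwhere(lm.labels == lab).astype(float)
        center = pts.mean(axis=0)
        if len(pts) > 400:
            pts = pts[rng.choice(len(pts), 400, replace=False)]
        # inlier band scaled to the spikelet's half-width: a tolerance much
        # thinner than the body makes the refit see only a slab of pixels
        # and wobbles by several degrees on short ellipses
        half_width = float(np.sqrt(np.linalg.eigvalsh(np.cov(pts.T))[0]) * 2.0)
        tol = max(cfg.ransac_tol_px, half_width)
        axes.append(
            ransac_major_axis(
                pts,
                iterations=cfg.ransac_iterations,
                inlier_tol_px=tol,
                seed=cfg.seed + lab,
            )
        )
        centers.append(center)
    traits: dict = {"count": lm.n_instances}
    ear_axis = None
    angles: list[float] = []
    if lm.n_instances >= cfg.ear_axis_degree + 1:
        ear_axis = _select_ear_axis(np.asarray(centers), cfg.ear_axis_degree)
        for line, center in zip(axes, centers):
            try:
                angles.append(spikelet_angle(line, ear_axis, center))
            except PhenoKitError:
                continue
        traits["ear_axis"] = {
            "degree": ear_axis.degree,
            "coefficients": ear_axis.coefficients.tolist(),
            "residual_rms_px": ear_axis.residual_rms,
            "domain": list(ear_axis.domain),
        }
        traits["spikelet_angles_deg"] = angles
        if angles:
            traits["median_spikelet_angle_deg"] = float(np.median(angles))
    skeleton = zhang_suen_thin(lm.mask())
    traits["skeleton_px"] = int(skeleton.sum())
    return PipelineResult(
        pipeline="spikelet",
        calibration=cal,
        traits=traits,
        provenance=_provenance(cfg, backend.name),
        records=records,
        labelmap=lm,
        artifacts={"skeleton": skeleton, "ear_axis": ear_axis, "axes": axes},
    )


def _select_ear_axis(centers: np.ndarray, max_degree: int):
    """Fit the rachis axis with the BIC-best polynomial degree <= max_degree.

    Spikelets attach alternately left/right of the rachis, so their midpoints
    zigzag around the true axis; a fixed high degree chases that zigzag and
    tilts the local tangents. BIC keeps a straight axis straight while still
    allowing real curvature.
    """
    n = len(centers)
    best = None
    for deg in range(1, max_degree + 1):
        if n < deg + 1:
            break
        axis = fit_ear_axis(centers, deg)
        rss = max(axis.residual_rms**2 * n, 1e-12)
        bic = n * np.log(rss / n) + (deg + 1) * np.log(n)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, axis)
    return best[1]


def run_canopy_pheno(image, config: PipelineConfig | None = None) -> PipelineResult:
    """Canopy analysis: green-HSV / intensity segmentation, largest
    component as the canopy, length/width/area/compactness plus green
    ratio of the canopy region."""
    cfg = config or PipelineConfig()
    img = as_rgb8(image)
    green_band = HSVBounds(cfg.green_lower, cfg.green_upper)
    mask = hsv_in_range(img, green_band) | otsu_binarize(img, invert=cfg.invert)
    mask = clean_mask(mask, cfg.min_area_px, cfg.opening_radius)
    lm = label_instances(mask, cfg.connectivity)
    cal = Calibration.none()
    if lm.n_instances == 0:
        return PipelineResult(
            pipeline="canopy",
            calibration=cal,
            traits={"count": 0, "area_px2": 0.0},
            provenance=_provenance(cfg, "hsv+otsu"),
            labelmap=lm,
        )
    areas = ndimage.sum_labels(
        np.ones_like(lm.labels), lm.labels, index=range(1, lm.n_instances + 1)
    )
    largest = int(np.argmax(areas)) + 1
    # fill interior speckle (shadowed pixels inside the crown) so area and
    # compactness describe the projected crown region
    canopy = ndimage.binary_fill_holes(lm.labels == largest)
    lm1 = LabelMap(labels=canopy.astype(np.int32), n_instances=1)
    rec = measure_instance(lm1, 1, cal)
    traits = {
        "count": 1,
        "area_px2": rec.area_px,
        "length_px": rec.length_px,
        "width_px": rec.width_px,
        "perimeter_px": rec.perimeter_px,
        "compactness": rec.compactness,
        "equivalent_diameter_px": rec.equivalent_diameter_px,
        "green_ratio": green_ratio(img, canopy, green_band),
    }
    return PipelineResult(
        pipeline="canopy",
        calibration=cal,
        traits=traits,
        provenance=_provenance(cfg, "hsv+otsu"),
        records=[rec],
        labelmap=lm1,
    )


def _load_points_csv(path) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path)
    if not {"x", "y"} <= set(df.columns):
        raise InvalidParameterError("points CSV needs 'x' and 'y' columns")
    return df[["x", "y"]].to_numpy(dtype=float)


def run_corn_pheno(
    source, config: PipelineConfig | None = None
) -> PipelineResult:
    """Maize kernel-row analysis: kernel centroids (from the classical
    yellow-blob backend, an (n, 2) array, or an x,y CSV) are PCA-aligned to
    the ear axis and clustered into rows; reports visible kernel count, row
    count and kernels per row."""
    cfg = config or PipelineConfig()
    backend_name = "points"
    if isinstance(source, (str, Path)):
        points = _load_points_csv(source)
        backend_name = "csv"
    else:
        arr = np.asarray(source)
        if arr.ndim == 3:  # an image: classical yellow-kernel blob detection
            mask = hsv_in_range(
                as_rgb8(arr), HSVBounds(cfg.kernel_hsv_lower, cfg.kernel_hsv_upper)
            )
            mask = clean_mask(mask, max(cfg.min_area_px // 2, 10), 0)
            lm = label_instances(mask, cfg.connectivity)
            lm = split_adhesions(
                lm, cfg.solidity_threshold, cfg.peak_min_distance, cfg.neck_ratio
            )
            points = np.asarray(
                [
                    np.argwhere(lm.labels == lab).mean(axis=0)[::-1]  # (x, y)
                    for lab in range(1, lm.n_instances + 1)
                ]
            ).reshape(-1, 2)
            backend_name = "blobs(hsv-yellow)"
        else:
            points = arr.astype(float)
    aligned = pca_align(points)
    assignments, k = cluster_rows(
        aligned, k_min=cfg.k_min, k_max=cfg.k_max, seed=cfg.seed
    )
    rf = extract_row_features(assignments, aligned)
    traits = rf.to_dict()
    traits["rotation_deg"] = aligned.rotation_deg
    if cfg.row_multiplier is not None:
        traits["estimated_total_row_count"] = int(
            round(rf.visible_row_count * cfg.row_multiplier)
        )
    return PipelineResult(
        pipeline="corn",
        calibration=Calibration.none(),
        traits=traits,
        provenance=_provenance(cfg, backend_name),
        artifacts={"aligned": aligned, "assignments": assignments},
    )


def _keypoints_from(source) -> KeypointTriple:
    if isinstance(source, KeypointTriple):
        return source
    if isinstance(source, dict):
        return KeypointTriple(
            A=tuple(source["A"]), B=tuple(source["B"]), C=tuple(source["C"]),
            L=tuple(source["L"]) if source.get("L") is not None else None,
        )
    if isinstance(source, (str, Path)):
        import pandas as pd

        df = pd.read_csv(source)
        if not {"x", "y", "role"} <= set(df.columns):
            raise InvalidParameterError("keypoint CSV needs x, y, role columns")
        pts = {r.role: (float(r.y), float(r.x)) for r in df.itertuples()}
        return KeypointTriple(
            A=pts["A"], B=pts["B"], C=pts["C"], L=pts.get("L")
        )
    raise InvalidParameterError("unsupported keypoint source")


def run_leaf_angle(source, config: PipelineConfig | None = None) -> PipelineResult:
    """Flag-leaf angle from wheat-organ keypoints (stem base A, spike tip B,
    leaf node C, leaf reference L), in the configured mode."""
    cfg = config or PipelineConfig()
    k = _keypoints_from(source)
    angle = flag_leaf_angle(k, mode=cfg.leaf_angle_mode)
    return PipelineResult(
        pipeline="leaf_angle",
        calibration=Calibration.none(),
        traits={"flag_leaf_angle_deg": angle, "mode": cfg.leaf_angle_mode},
        provenance=_provenance(cfg, "keypoints"),
    )


def run_wheat_head(image, config: PipelineConfig | None = None) -> PipelineResult:
    """Field-plot analysis: white-marker detection and verification,
    perspective rectification, head enumeration inside the marked area,
    head length/width, density (heads/m^2) and an optional yield estimate
    (requires an explicit per-head grain weight)."""
    cfg = config or PipelineConfig()
    img = as_rgb8(image)
    try:
        marker = detect_rect_marker(
            img,
            whiteness_threshold=cfg.whiteness_threshold,
            real_width_m=cfg.marker_width_m,
            real_height_m=cfg.marker_height_m,
            right_angle_tol_deg=cfg.right_angle_tol_deg,
        )
    except PhenoKitError:
        marker = None
    if marker is None:
        lm, records = _heads_in(img, None, cfg)
        traits = {"count": lm.n_instances, "calibrated": False}
        return PipelineResult(
            pipeline="wheat_head",
            calibration=Calibration.none(),
            traits=traits,
            provenance=_provenance(cfg, "blobs(otsu)"),
            records=records,
            labelmap=lm,
        )
    rect = rectify_from_marker(img, marker)
    lm, records = _heads_in(rect.image, rect.marker_corners, cfg, cal=rect.calibration)
    area_m2 = cfg.marker_width_m * cfg.marker_height_m
    density = lm.n_instances / area_m2
    summary = summarize_scene(records, rect.calibration)
    traits = {
        "count": lm.n_instances,
        "density_per_m2": density,
        "marker_area_m2": area_m2,
        "head_summary": summary.to_dict(),
    }
    if cfg.grain_weight_g_per_head is not None:
        # g/m^2 -> kg/ha: x 10^4 m^2/ha / 10^3 g/kg
        traits["yield_kg_per_ha"] = density * cfg.grain_weight_g_per_head * 10.0
    return PipelineResult(
        pipeline="wheat_head",
        calibration=rect.calibration,
        traits=traits,
        provenance=_provenance(cfg, "blobs(otsu)"),
        records=records,
        labelmap=lm,
        artifacts={"rectified": rect.image, "marker": marker, "transform": rect.transform},
    )


def _heads_in(image, marker_corners, cfg: PipelineConfig, cal=None):
    """Label head-like blobs, optionally restricted to inside a rectified
    marker quad (excluding the white frame itself)."""
    img = as_rgb8(image)
    lum = luminance8(img)
    white = np.min(img, axis=-1) >= cfg.whiteness_threshold
    region = np.ones(lum.shape, dtype=bool)
    if marker_corners is not None:
        r0 = int(np.floor(marker_corners[:, 0].min())) + 2
        r1 = int(np.ceil(marker_corners[:, 0].max())) - 2
        c0 = int(np.floor(marker_corners[:, 1].min())) + 2
        c1 = int(np.ceil(marker_corners[:, 1].max())) - 2
        region[:] = False
        region[max(r0, 0) : r1, max(c0, 0) : c1] = True
    sel = region & ~ndimage.binary_dilation(white, iterations=3)
    vals = lum[sel]
    empty = LabelMap(labels=np.zeros_like(lum, dtype=np.int32), n_instances=0)
    if vals.size == 0:
        return empty, []
    hist = np.bincount(vals.ravel(), minlength=256)
    # a near-unimodal histogram means the region holds no objects, only noise
    if otsu_effectiveness(hist) < cfg.head_bimodality_min:
        return empty, []
    t = otsu_threshold(hist)
    mask = (lum > t) & sel
    mask = clean_mask(mask, cfg.head_min_area_px, 0)
    lm = label_instances(mask, cfg.connectivity)
    # rectification blur can fuse adjacent heads; resolve like any adhesion
    lm = split_adhesions(lm, cfg.solidity_threshold, cfg.peak_min_distance, cfg.neck_ratio)
    cal = cal or Calibration.none()
    records = _measure_all(lm, cal)
    return lm, records


PIPELINES = {
    "seed": run_seed_pheno,
    "tomato": run_tomato_pheno,
    "spikelet": run_spikelet_pheno,
    "canopy": run_canopy_pheno,
    "corn": run_corn_pheno,
    "leaf_angle": run_leaf_angle,
    "wheat_head": run_wheat_head,
}
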