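"""Instance segmentation for top-down phenotyping scenes.

Classical route: global intensity thresholding (between-class-variance
criterion) or bounded-HSV color thresholding, morphological cleanup,
connected-component labeling, and watershed splitting of touching objects
gated on convex-hull solidity. This is the reference backend standing behind
the pluggable detection contract used by the pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color, measure, morphology
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from ._raster import as_rgb8, luminance8, trace_contour
from .errors import InvalidParameterError

__all__ = [
    "BinaryMask",
    "LabelMap",
    "HSVBounds",
    "otsu_threshold",
    "otsu_binarize",
    "hsv_in_range",
    "clean_mask",
    "label_instances",
    "split_adhesions",
]

# a BinaryMask is simply a 2-D boolean ndarray; no wrapper class is needed
BinaryMask = np.ndarray


@dataclass(frozen=True)
class HSVBounds:
    """Inclusive per-channel HSV bounds.

    Hue in degrees [0, 360); saturation/value in [0, 1]. A lower hue greater
    than the upper hue denotes an interval wrapping through 0 deg (e.g. the
    red band [340, 20]).
    """

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]

    def __post_init__(self) -> None:
        for i, name in ((1, "saturation"), (2, "value")):
            if self.lower[i] > self.upper[i]:
                raise InvalidParameterError(f"{name} lower bound exceeds upper bound")
            if not (0 <= self.lower[i] <= 1 and 0 <= self.upper[i] <= 1):
                raise InvalidParameterError(f"{name} bounds must lie in [0, 1]")


@dataclass
class LabelMap:
    """Integer instance-label raster: 0 = background, labels 1..n contiguous."""

    labels: np.ndarray
    n_instances: int

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "LabelMap":
        """Wrap a label raster, renumbering labels to 1..n if not contiguous."""
        labels = np.asarray(labels)
        vals = np.unique(labels)
        vals = vals[vals > 0]
        if len(vals) and vals[-1] != len(vals):
            labels = _renumber(labels)
        return cls(labels=labels.astype(np.int32), n_instances=len(vals))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, label: int | None = None) -> np.ndarray:
        if label is None:
            return self.labels > 0
        return self.labels == label

    def contour(self, label: int) -> np.ndarray:
        """Closed outer-boundary polygon of one instance, (N, 2) (row, col)."""
        inst = self.labels == label
        if not inst.any():
            raise InvalidParameterError(f"label {label} not present")
        return trace_contour(inst)

    def contours(self) -> dict[int, np.ndarray]:
        return {lab: self.contour(lab) for lab in range(1, self.n_instances + 1)}


def _renumber(labels: np.ndarray) -> np.ndarray:
    vals = np.unique(labels)
    vals = vals[vals > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(vals, start=1):
        out[labels == old] = new
    return out


def otsu_threshold(gray_histogram: np.ndarray) -> int:
    """Threshold level maximizing between-class variance.

    Given 256 gray-level counts, returns the level ``t`` maximizing
    ``w0(t) * w1(t) * (mu0(t) - mu1(t))**2`` where class 0 is levels <= t and
    class 1 is levels > t (foreground = pixels strictly above t). Ties are
    broken by the lowest qualifying t.
    """
    hist = np.asarray(gray_histogram, dtype=np.float64)
    if hist.ndim != 1 or len(hist) != 256:
        raise InvalidParameterError("histogram must have 256 bins")
    if hist.sum() <= 0 or (hist < 0).any():
        raise InvalidParameterError("histogram must contain nonnegative counts, not all zero")
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)  # mass at levels <= t
    m0 = np.cumsum(hist * levels)  # first moment at levels <= t
    w1 = total - w0
    mu_total = m0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = np.where(w0 > 0, m0 / w0, 0.0)
        mean1 = np.where(w1 > 0, (mu_total - m0) / w1, 0.0)
    crit = w0 / total * w1 / total * (mean0 - mean1) ** 2
    crit[w1 == 0] = 0.0
    crit[w0 == 0] = 0.0
    return int(np.argmax(crit))  # argmax takes the first (lowest) maximizer


def otsu_effectiveness(gray_histogram: np.ndarray) -> float:
    """Otsu's effectiveness metric: between-class variance at the chosen
    threshold over total variance, in [0, 1].

    Near-unimodal (e.g. pure-noise) histograms score low; well-separated
    foreground/background scores near 1. Useful as a guard before trusting a
    global threshold on a region that may contain no objects at all.
    """
    hist = np.asarray(gray_histogram, dtype=np.float64)
    t = otsu_threshold(hist)
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    mu = (hist * levels).sum() / total
    var_total = (hist * (levels - mu) ** 2).sum() / total
    if var_total == 0:
        return 0.0
    w0 = hist[: t + 1].sum() / total
    w1 = 1.0 - w0
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / (w0 * total)
    mu1 = (hist[t + 1 :] * levels[t + 1 :]).sum() / (w1 * total)
    return float(w0 * w1 * (mu0 - mu1) ** 2 / var_total)


def otsu_binarize(image: np.ndarray, invert: bool = False) -> BinaryMask:
    """Binarize the luminance channel at the between-class-variance optimum.

    Foreground = pixels strictly brighter than the threshold (objects against
    the recommended dark background); pass ``invert=True`` for bright
    backgrounds.
    """
    lum = luminance8(image)
    t = otsu_threshold(np.bincount(lum.ravel(), minlength=256))
    mask = lum > t
    return ~mask if invert else mask


def hsv_in_range(image: np.ndarray, bounds: HSVBounds) -> BinaryMask:
    """Boolean mask of pixels whose HSV falls inside ``bounds``.

    The hue test honours wraparound intervals (lower hue > upper hue).
    """
    rgb = as_rgb8(image)
    hsv = color.rgb2hsv(rgb)
    h = hsv[..., 0] * 360.0
    s = hsv[..., 1]
    v = hsv[..., 2]
    lo, hi = bounds.lower, bounds.upper
    if lo[0] <= hi[0]:
        h_ok = (h >= lo[0]) & (h <= hi[0])
    else:  # wrapped through 0 deg
        h_ok = (h >= lo[0]) | (h <= hi[0])
    return h_ok & (s >= lo[1]) & (s <= hi[1]) & (v >= lo[2]) & (v <= hi[2])


def clean_mask(
    mask: BinaryMask, min_area_px: int = 0, opening_radius: int = 0
) -> BinaryMask:
    """Morphological opening (disc element) then small-component removal."""
    if min_area_px < 0:
        raise InvalidParameterError("min_area_px must be >= 0")
    out = np.asarray(mask).astype(bool)
    if opening_radius > 0:
        out = morphology.opening(out, morphology.disk(opening_radius))
    if min_area_px > 0:
        # remove components strictly smaller than min_area_px
        out = morphology.remove_small_objects(
            out, max_size=min_area_px - 1, connectivity=2
        )
    return out


def label_instances(mask: BinaryMask, connectivity: int = 8) -> LabelMap:
    """Connected-component labeling (4- or 8-connectivity)."""
    if connectivity not in (4, 8):
        raise InvalidParameterError("connectivity must be 4 or 8")
    skconn = 1 if connectivity == 4 else 2
    labels = measure.label(np.asarray(mask).astype(bool), connectivity=skconn)
    return LabelMap(labels=labels.astype(np.int32), n_instances=int(labels.max(initial=0)))


def split_adhesions(
    labelmap: LabelMap,
    solidity_threshold: float = 0.97,
    peak_min_distance: int = 6,
    neck_ratio: float = 0.9,
) -> LabelMap:
    """Split fused instances with the distance-transform watershed.

    Instances whose convex-hull solidity falls below ``solidity_threshold``
    (concavities typical of touching objects) are re-segmented: the Euclidean
    distance transform of the instance mask is computed, its local maxima at
    least ``peak_min_distance`` apart become watershed markers, and the
    marker-controlled watershed of the negated distance transform partitions
    the instance.

    A candidate cut is only kept when it crosses a genuine constriction:
    adjacent watershed pieces are merged back whenever the distance-transform
    value on their shared ridge exceeds ``neck_ratio`` times the smaller of
    their peak values. Small rasterized ellipses can dip below any solidity
    threshold that still catches deeply fused pairs — the two distributions
    overlap — so this neck test, not solidity alone, decides the split.

    Solid instances pass through unchanged. The union of foreground pixels
    is preserved exactly and labels are renumbered contiguously.
    """
    labels = labelmap.labels
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for region in measure.regionprops(labels):
        sl = region.slice
        inst = labels[sl] == region.label
        pieces = [inst]
        if region.solidity < solidity_threshold:
            dist = ndimage.distance_transform_edt(np.pad(inst, 1))[1:-1, 1:-1]
            peaks = peak_local_max(
                dist,
                min_distance=int(peak_min_distance),
                exclude_border=False,
                labels=inst,
            )
            if len(peaks) >= 2:
                markers = np.zeros(inst.shape, dtype=np.int32)
                markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
                ws = watershed(-dist, markers=markers, mask=inst, connectivity=2)
                ws = _merge_shallow_necks(ws, dist, neck_ratio)
                pieces = [ws == k for k in np.unique(ws) if k > 0]
        for piece in pieces:
            out[sl][piece] = next_label
            next_label += 1
    return LabelMap(labels=out, n_instances=next_label - 1)


def _merge_shallow_necks(ws: np.ndarray, dist: np.ndarray, neck_ratio: float) -> np.ndarray:
    """Union adjacent watershed pieces whose shared ridge is not a real neck."""
    ids = [k for k in np.unique(ws) if k > 0]
    if len(ids) < 2:
        return ws
    peak = {k: float(dist[ws == k].max()) for k in ids}
    parent = {k: k for k in ids}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    struct = np.ones((3, 3), bool)
    for i, k in enumerate(ids):
        grown = ndimage.binary_dilation(ws == k, structure=struct)
        for k2 in ids[i + 1 :]:
            shared = grown & (ws == k2)
            if not shared.any():
                continue
            neck = float(dist[shared].max())
            if neck > neck_ratio * min(peak[k], peak[k2]):
                a, b = find(k), find(k2)
                if a != b:
                    parent[b] = a
    merged = ws.copy()
    for k in ids:
        merged[ws == k] = find(k)
    return merged
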