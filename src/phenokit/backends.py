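"""Pluggable detection-backend contract with classical reference backends.

The trait pipelines consume detections (an instance mask or a set of center
points) through this narrow contract, so any detector — including learned
ones running elsewhere — can stand in front of the classical measurement
code. The defaults here are fully classical: global intensity thresholding
for bright objects on dark backgrounds, and bounded-HSV color thresholding
for colored objects (red fruit, yellow kernels).

A backend declares its ``capability`` ("mask" or "points") and must be
deterministic for a fixed configuration; its ``name`` is recorded in result
provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .segmentation import (
    HSVBounds,
    clean_mask,
    hsv_in_range,
    label_instances,
    otsu_binarize,
)

__all__ = ["DetectionBackend", "OtsuMaskBackend", "HsvMaskBackend", "BlobPointsBackend"]


@runtime_checkable
class DetectionBackend(Protocol):
    """Contract: ``detect(image)`` returns a boolean mask (capability
    "mask") or an (n, 2) float array of (x, y) centers (capability
    "points"), always inside image bounds."""

    name: str
    capability: str

    def detect(self, image: np.ndarray): ...


@dataclass(frozen=True)
class OtsuMaskBackend:
    """Foreground mask via the between-class-variance threshold on luminance."""

    invert: bool = False
    name: str = "otsu"
    capability: str = "mask"

    def detect(self, image: np.ndarray) -> np.ndarray:
        return otsu_binarize(image, invert=self.invert)


@dataclass(frozen=True)
class HsvMaskBackend:
    """Foreground mask via inclusive HSV bounds (wrap-aware hue)."""

    bounds: HSVBounds = field(
        default_factory=lambda: HSVBounds((340.0, 0.35, 0.20), (20.0, 1.0, 1.0))
    )
    name: str = "hsv"
    capability: str = "mask"

    def detect(self, image: np.ndarray) -> np.ndarray:
        return hsv_in_range(image, self.bounds)


@dataclass(frozen=True)
class BlobPointsBackend:
    """Center points of connected blobs of a mask backend's foreground."""

    mask_backend: DetectionBackend = field(default_factory=OtsuMaskBackend)
    min_area_px: int = 20
    opening_radius: int = 0
    capability: str = "points"

    @property
    def name(self) -> str:
        return f"blobs({self.mask_backend.name})"

    def detect(self, image: np.ndarray) -> np.ndarray:
        mask = clean_mask(
            self.mask_backend.detect(image), self.min_area_px, self.opening_radius
        )
        lm = label_instances(mask, connectivity=8)
        pts = []
        for lab in range(1, lm.n_instances + 1):
            rc = np.argwhere(lm.labels == lab)
            pts.append([rc[:, 1].mean(), rc[:, 0].mean()])  # (x, y)
        return np.asarray(pts, dtype=float).reshape(-1, 2)
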