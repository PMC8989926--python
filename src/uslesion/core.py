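"""Geometry primitives shared by every pipeline stage.

Coordinate convention: 0-based, ``x`` increases rightward along columns and
``y`` downward along rows.  A box ``(x, y, w, h)`` covers the half-open pixel
set ``[x, x+w) x [y, y+h)``, so integer boxes have exact pixel areas and the
upper-left vertex is ``(x, y)``.  Coordinates may be fractional: the iterative
bounding-box regression produces real-valued boxes, and all overlap measures
here are continuous-area computations (no rasterisation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "BBox",
    "Delta",
    "PipelineConfig",
    "box_jaccard",
    "intersection_box",
    "enclosing_box",
    "mask_to_bbox",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box: upper-left vertex ``(x, y)``, width ``w``, height ``h``.

    ``confidence`` optionally carries the lesion probability attached by the
    RoI classifier; it travels with the box through regression and
    aggregation.
    """

    x: float
    y: float
    w: float
    h: float
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("x", "y", "w", "h"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"BBox.{name} must be finite, got {v!r}")
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"BBox requires w > 0 and h > 0, got w={self.w}, h={self.h}")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def with_confidence(self, confidence: Optional[float]) -> "BBox":
        return replace(self, confidence=confidence)

    def round(self) -> "BBox":
        """Nearest-integer box (used when cropping pixels)."""
        return BBox(round(self.x), round(self.y), max(1.0, round(self.w)),
                    max(1.0, round(self.h)), self.confidence)


@dataclass(frozen=True)
class Delta:
    """Regression offset between a box and a target.

    ``t_x``/``t_y`` are translations in units of the source box's width and
    height; ``t_w``/``t_h`` are natural-log size ratios.
    """

    t_x: float
    t_y: float
    t_w: float
    t_h: float

    def __post_init__(self) -> None:
        for name in ("t_x", "t_y", "t_w", "t_h"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"Delta.{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.t_x, self.t_y, self.t_w, self.t_h], dtype=float)


@dataclass
class PipelineConfig:
    """Scalar knobs of the full detection chain.

    The gate/bound values (0.9, 0.2, 0.5, 0.7) and the 30% bottom clip are the
    method's published operating points; the rest are implementation defaults.
    """

    clip_fraction: float = 0.3          # fraction of bottom rows removed
    classifier_gate: float = 0.9        # keep RoIs with p_lesion strictly above
    background_jaccard: float = 0.2     # B_bg membership bound (loss indicator)
    cluster_jaccard: float = 0.5        # aggregation cluster-entry bound
    intersect_jaccard: float = 0.7      # aggregation intersection-branch bound
    tp_jaccard: float = 0.5             # evaluation TP bound
    total_steps: int = 4                # regression iterations S
    canny_low: float = 0.08             # hysteresis low threshold (gradient units)
    canny_high: float = 0.18            # hysteresis high threshold
    gaussian_sigma: float = 1.0         # Canny pre-smoothing scale, px
    wavelet_name: str = "db4"
    wavelet_levels: int = 3
    min_roi_px: int = 10                # proposals below min_roi_px x min_roi_px dropped
    max_roi_frame_fraction: float = 0.95
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.clip_fraction < 1.0):
            raise ValueError("clip_fraction must lie in (0, 1)")
        if not (0.0 < self.background_jaccard < self.cluster_jaccard
                <= self.intersect_jaccard <= 1.0):
            raise ValueError(
                "require 0 < background_jaccard < cluster_jaccard "
                "<= intersect_jaccard <= 1")
        if self.total_steps < 1:
            raise ValueError("total_steps must be >= 1")
        if self.canny_low >= self.canny_high:
            raise ValueError("canny_low must be < canny_high")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def intersection_box(a: BBox, b: BBox) -> Optional[BBox]:
    """Intersection rectangle of two boxes, or ``None`` if they are disjoint."""
    x1 = max(a.x, b.x)
    y1 = max(a.y, b.y)
    x2 = min(a.x2, b.x2)
    y2 = min(a.y2, b.y2)
    if x2 <= x1 or y2 <= y1:
        return None
    return BBox(x1, y1, x2 - x1, y2 - y1)


def enclosing_box(a: BBox, b: BBox) -> BBox:
    """Smallest axis-aligned box covering both inputs."""
    x1 = min(a.x, b.x)
    y1 = min(a.y, b.y)
    x2 = max(a.x2, b.x2)
    y2 = max(a.y2, b.y2)
    return BBox(x1, y1, x2 - x1, y2 - y1)


def box_jaccard(a: BBox, b: BBox) -> float:
    """Continuous-area Jaccard (intersection over union) of two boxes.

    Under the half-open convention this agrees exactly with the pixel-set
    Jaccard for integer boxes.  Disjoint boxes score 0.
    """
    iw = min(a.x2, b.x2) - max(a.x, b.x)
    ih = min(a.y2, b.y2) - max(a.y, b.y)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    return inter / union


def mask_to_bbox(mask: np.ndarray) -> BBox:
    """Tightest integer box containing every foreground (nonzero) pixel.

    This is the ground-truth conversion applied to binary lesion masks.
    Raises ``ValueError`` on an empty mask ("no lesion in mask").
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("no lesion in mask: mask has no foreground pixel")
    y = int(rows.min())
    x = int(cols.min())
    h = int(rows.max()) - y + 1
    w = int(cols.max()) - x + 1
    return BBox(float(x), float(y), float(w), float(h))
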