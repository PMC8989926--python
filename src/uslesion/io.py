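"""Reading and writing images, masks, and detection records.

Images are plain 2-D numpy arrays — ``uint8`` for raw 0–255 data, ``float64``
in [0, 1] after normalisation — which is the representation every stage of the
pipeline consumes.  Detections are JSON lists of records
``{"image_id", "x", "y", "w", "h", "confidence"}``; an optional CSV export
uses the same columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image as PILImage

from .core import BBox

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "DetectionRecord",
    "write_detections",
    "read_detections",
    "write_detections_csv",
]

_CSV_COLUMNS = ["image_id", "x", "y", "w", "h", "confidence"]


def read_image(path) -> np.ndarray:
    """Load a grayscale PNG/TIFF as a 2-D uint8 array.

    Multichannel inputs are converted to luminance; missing files raise
    ``FileNotFoundError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    with PILImage.open(path) as im:
        im = im.convert("L")
        arr = np.asarray(im, dtype=np.uint8)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    return arr


def write_image(img: np.ndarray, path) -> None:
    """Save a 2-D array as 8-bit grayscale PNG; floats are assumed in [0, 1]."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr.astype(float) * 255.0), 0, 255).astype(np.uint8)
    PILImage.fromarray(arr, mode="L").save(Path(path))


def read_mask(path) -> np.ndarray:
    """Load a binary lesion mask (foreground = any nonzero pixel)."""
    return read_image(path) > 0


def write_mask(mask: np.ndarray, path) -> None:
    write_image(np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8), path)


class DetectionRecord(dict):
    """A detection as a plain dict with validated geometry."""

    @classmethod
    def from_box(cls, image_id: str, box: BBox) -> "DetectionRecord":
        return cls(image_id=str(image_id), x=float(box.x), y=float(box.y),
                   w=float(box.w), h=float(box.h),
                   confidence=None if box.confidence is None else float(box.confidence))

    def to_box(self) -> BBox:
        return BBox(self["x"], self["y"], self["w"], self["h"],
                    confidence=self.get("confidence"))


def _validate_record(rec: dict) -> DetectionRecord:
    missing = {"image_id", "x", "y", "w", "h"} - set(rec)
    if missing:
        raise ValueError(f"malformed detection record, missing keys {sorted(missing)}: {rec}")
    if rec["w"] <= 0 or rec["h"] <= 0:
        raise ValueError(f"invalid detection record (w, h must be positive): {rec}")
    out = DetectionRecord(image_id=str(rec["image_id"]), x=float(rec["x"]),
                          y=float(rec["y"]), w=float(rec["w"]), h=float(rec["h"]),
                          confidence=rec.get("confidence"))
    out.to_box()  # confidence range check
    return out


def write_detections(records: Sequence[dict], path) -> None:
    """Serialise detection records as a JSON list (empty list is valid)."""
    records = [_validate_record(dict(r)) for r in records]
    Path(path).write_text(json.dumps([dict(r) for r in records], indent=1) + "\n")


def read_detections(path) -> list[DetectionRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"detections file not found: {path}")
    data = json.loads(path.read_text())
    if not isinstance(data, list):
        raise ValueError(f"malformed detections file (expected a JSON list): {path}")
    return [_validate_record(rec) for rec in data]


def write_detections_csv(records: Sequence[dict], path) -> None:
    records = [_validate_record(dict(r)) for r in records]
    pd.DataFrame(list(records), columns=_CSV_COLUMNS).to_csv(path, index=False)
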