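"""Pre-processing chain applied before region proposal.

Order is fixed: histogram equalization -> min-max normalization -> wavelet
denoising -> bottom clipping.  Equalization spreads the compressed dynamic
range typical of ultrasound displays; the wavelet shrinkage suppresses the
high-frequency component of speckle; the clip removes the bottom rows
(posterior field, mostly shadow and reverberation) to cut down redundant RoI
candidates.  Lesions in breast scans sit predominantly in the upper part of
the frame, so the clip does not touch the truth region.

Clipping keeps the top rows, so box coordinates measured on the clipped image
are valid in the original frame without any shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from skimage.restoration import denoise_wavelet

from .core import PipelineConfig

__all__ = [
    "PreprocessResult",
    "equalize_histogram",
    "normalize",
    "wavelet_denoise",
    "clip_bottom",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessResult:
    """Processed image plus the clip bookkeeping.

    ``row_offset`` is the shift to add to y-coordinates measured on the
    clipped image to recover original coordinates; top rows are kept, so it
    is always 0 and exists only to make the mapping explicit.
    """

    image: np.ndarray
    kept_rows: int
    row_offset: int = 0
    full_image: np.ndarray | None = None  # same processing, without the clip


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Global histogram equalization of an 8-bit image.

    Classic CDF remapping: level v maps to
    ``round(255 * (cdf(v) - cdf_min) / (n_pixels - cdf_min))``.  A constant
    image has a single level and is returned unchanged; with >= 2 levels the
    output spans the full 0–255 scale.
    """
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        raise ValueError("equalize_histogram expects an 8-bit (uint8) image")
    hist = np.bincount(arr.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    nonzero = np.nonzero(hist)[0]
    if nonzero.size <= 1:
        return arr.copy()
    cdf_min = cdf[nonzero[0]]
    lut = np.round((cdf - cdf_min) * 255.0 / (arr.size - cdf_min)).astype(np.uint8)
    return lut[arr]


def normalize(img: np.ndarray) -> np.ndarray:
    """Linear per-image rescale to [0, 1]; a constant image maps to zeros."""
    arr = np.asarray(img, dtype=float)
    lo = arr.min()
    hi = arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def wavelet_denoise(img: np.ndarray, wavelet_name: str = "db4",
                    levels: int = 3) -> np.ndarray:
    """Soft-threshold wavelet shrinkage (BayesShrink) of a normalized image.

    Detail coefficients of a ``levels``-deep multilevel decomposition are
    shrunk with a per-subband Bayes threshold and the image reconstructed.
    Raises if the requested depth exceeds what the image size supports.
    """
    arr = np.asarray(img, dtype=float)
    wav = pywt.Wavelet(wavelet_name)
    max_level = pywt.dwtn_max_level(arr.shape, wav)
    if levels > max_level:
        raise ValueError(
            f"{levels} wavelet levels too deep for image shape {arr.shape} "
            f"with '{wavelet_name}' (max {max_level})")
    if not np.any(arr != arr.flat[0]):
        return arr.copy()  # constant input: nothing to shrink
    out = denoise_wavelet(arr, wavelet=wavelet_name, wavelet_levels=levels,
                          method="BayesShrink", mode="soft", rescale_sigma=True)
    return np.clip(out, 0.0, 1.0)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def clip_bottom(img: np.ndarray, clip_fraction: float,
                full_image: np.ndarray | None = None) -> PreprocessResult:
    """Drop the bottom ``clip_fraction`` of rows.

    Keeps the top ``round((1 - clip_fraction) * H)`` rows (round half away
    from zero).  Raises when nothing would remain.
    """
    if not (0.0 <= clip_fraction < 1.0):
        raise ValueError("clip_fraction must lie in [0, 1)")
    arr = np.asarray(img)
    kept = _round_half_away((1.0 - clip_fraction) * arr.shape[0])
    if kept < 1:
        raise ValueError(f"clip of {clip_fraction} would leave 0 of "
                         f"{arr.shape[0]} rows")
    return PreprocessResult(image=arr[:kept].copy(), kept_rows=kept,
                            row_offset=0, full_image=full_image)


def preprocess(img: np.ndarray, cfg: PipelineConfig | None = None,
               clip: bool = True) -> PreprocessResult:
    """Full chain: equalize -> normalize -> denoise -> clip.

    With ``clip=False`` (normal-image experiments) the full-height processed
    image is returned with ``kept_rows`` equal to the height.
    """
    cfg = cfg or PipelineConfig()
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(np.asarray(arr, dtype=float)
                               * (255.0 if arr.max() <= 1.0 else 1.0)),
                      0, 255).astype(np.uint8)
    eq = equalize_histogram(arr)
    norm = normalize(eq)
    den = wavelet_denoise(norm, cfg.wavelet_name, cfg.wavelet_levels)
    if not clip:
        return PreprocessResult(image=den, kept_rows=den.shape[0],
                                row_offset=0, full_image=den)
    return clip_bottom(den, cfg.clip_fraction, full_image=den)
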