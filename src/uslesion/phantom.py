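"""Seeded ultrasound-like phantom generator.

Each phantom is a smoothly heterogeneous tissue field multiplied by
unit-mean gamma speckle, with a hypoechoic (darker) elliptical lesion, an
optional acoustic-shadow streak distal to the lesion, and a dark posterior
band across the bottom rows (the part the preprocessing clip removes).  This
is a first-order appearance model — multiplicative granular noise, lesion
contrast, posterior artifacts — not a physical wave simulation.

Lesions are always placed above the posterior band, mirroring the anatomical
prior that breast masses sit in the upper part of the scan, so the bottom
clip never removes truth.  Everything is driven by one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BBox, mask_to_bbox
from . import io as usio

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class PhantomConfig:
    height: int = 128
    width: int = 128
    lesion_center: Optional[tuple[float, float]] = (60.0, 44.0)  # (col, row); None = no lesion
    lesion_axes: tuple[float, float] = (14.0, 10.0)              # semi-axes, px
    lesion_angle: float = 0.0                                    # radians
    background_level: float = 0.55    # mean echogenicity of tissue, [0, 1]
    lesion_level: float = 0.22        # hypoechoic: strictly below background
    heterogeneity: float = 0.06       # sd of the smooth tissue variation
    speckle_shape: float = 25.0       # gamma shape k; sd/mean = 1/sqrt(k)
    shadow: bool = False
    shadow_strength: float = 0.6      # multiplicative attenuation in the streak
    shadow_width_fraction: float = 0.6  # streak width / lesion width
    posterior_band_fraction: float = 0.3
    posterior_level: float = 0.35     # multiplicative attenuation of the band
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("phantom must be at least 16x16")
        if not (0.0 < self.posterior_band_fraction < 1.0):
            raise ValueError("posterior_band_fraction must lie in (0, 1)")
        if self.lesion_center is not None:
            if self.lesion_level >= self.background_level:
                raise ValueError("lesion must be hypoechoic: "
                                 "lesion_level < background_level")
            if min(self.lesion_axes) < 4:
                raise ValueError("lesion semi-axes must be at least 4 px")
            cx, cy = self.lesion_center
            a, b = self.lesion_axes
            reach = max(a, b)
            top_rows = (1.0 - self.posterior_band_fraction) * self.height
            if (cy - reach < 0 or cy + reach > top_rows
                    or cx - reach < 0 or cx + reach > self.width):
                raise ValueError(
                    "lesion out of bounds: the ellipse must lie entirely in "
                    f"the top {top_rows:.0f} rows of the {self.height}x"
                    f"{self.width} frame")


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray              # uint8, the pipeline input
    mask: np.ndarray               # bool lesion raster (all-False when no lesion)
    truth_box: Optional[BBox]      # mask_to_bbox(mask); None for normal phantoms
    config: PhantomConfig
    clean_field: np.ndarray = field(repr=False, default=None)  # pre-speckle float field
    image_float: np.ndarray = field(repr=False, default=None)  # clean_field * speckle


def _ellipse_indicator(cfg: PhantomConfig) -> np.ndarray:
    rows, cols = np.indices((cfg.height, cfg.width))
    cx, cy = cfg.lesion_center
    a, b = cfg.lesion_axes
    ca, sa = np.cos(cfg.lesion_angle), np.sin(cfg.lesion_angle)
    u = (cols - cx) * ca + (rows - cy) * sa
    v = -(cols - cx) * sa + (rows - cy) * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(cfg: PhantomConfig) -> PhantomSample:
    """One phantom, bit-reproducible from ``cfg.seed``.

    The clean field (tissue + lesion + shadow + posterior band) is built
    deterministically, then multiplied by unit-mean gamma speckle; the 8-bit
    image is the clipped, quantized product.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.height, cfg.width)

    het = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), 8.0)
    sd = het.std()
    if sd > 0:
        het *= cfg.heterogeneity / sd
    clean = cfg.background_level + het

    if cfg.lesion_center is not None:
        mask = _ellipse_indicator(cfg)
        soft = ndimage.gaussian_filter(mask.astype(float), 1.0)
        clean = clean * (1.0 - soft) + cfg.lesion_level * soft
        if cfg.shadow:
            cx, _ = cfg.lesion_center
            a, b = cfg.lesion_axes
            reach = max(a, b)
            half = cfg.shadow_width_fraction * max(a, b)
            cols = np.arange(cfg.width)
            in_streak = np.abs(cols - cx) <= half
            rows = np.arange(cfg.height)
            below = rows > cfg.lesion_center[1] + reach
            streak = np.outer(below, in_streak).astype(float)
            streak = ndimage.gaussian_filter(streak, 1.5)
            clean = clean * (1.0 - streak * (1.0 - cfg.shadow_strength))
        truth = mask_to_bbox(mask)
    else:
        mask = np.zeros(shape, dtype=bool)
        truth = None

    band_start = int(round((1.0 - cfg.posterior_band_fraction) * cfg.height))
    band = np.ones(cfg.height)
    band[band_start:] = cfg.posterior_level
    band = ndimage.gaussian_filter1d(band, 1.5)
    clean = clean * band[:, None]
    clean = np.clip(clean, 0.02, 1.0)

    k = cfg.speckle_shape
    speckle = rng.gamma(shape=k, scale=1.0 / k, size=shape)
    img_float = clean * speckle
    image = np.clip(np.round(img_float * 255.0), 0, 255).astype(np.uint8)
    return PhantomSample(image=image, mask=mask, truth_box=truth, config=cfg,
                         clean_field=clean, image_float=img_float)


_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "axis_major": (9.0, 18.0),
    "axis_ratio": (0.55, 0.95),
    "angle": (0.0, np.pi),
    "lesion_level": (0.16, 0.30),
    "background_level": (0.48, 0.62),
}


def generate_dataset(n: int, cfg_ranges: Optional[dict] = None, seed: int = 0,
                     normal_fraction: float = 0.0,
                     base: Optional[PhantomConfig] = None,
                     shadow_fraction: float = 0.25,
                     ) -> tuple[list[PhantomSample], pd.DataFrame]:
    """Draw ``n`` phantoms with geometry sampled from stated ranges.

    Exactly ``round(normal_fraction * n)`` samples are lesion-free, their
    positions chosen by the seeded generator.  Returns the samples and a
    manifest with one row of generation parameters per sample.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(_DEFAULT_RANGES)
    if cfg_ranges:
        unknown = set(cfg_ranges) - set(ranges)
        if unknown:
            raise ValueError(f"unknown cfg_ranges keys: {sorted(unknown)}")
        ranges.update(cfg_ranges)
    for key, (lo, hi) in ranges.items():
        if not (lo <= hi):
            raise ValueError(f"invalid range for {key}: ({lo}, {hi})")
    base = base or PhantomConfig()
    rng = np.random.default_rng(seed)
    n_normal = int(round(normal_fraction * n))
    normal_idx = set(rng.choice(n, size=n_normal, replace=False).tolist())

    samples: list[PhantomSample] = []
    rows = []
    top_rows = (1.0 - base.posterior_band_fraction) * base.height
    for i in range(n):
        sample_seed = int(rng.integers(0, 2**31 - 1))
        if i in normal_idx:
            cfg = replace(base, lesion_center=None, seed=sample_seed,
                          shadow=False)
        else:
            a = rng.uniform(*ranges["axis_major"])
            b = a * rng.uniform(*ranges["axis_ratio"])
            reach = a
            cx = rng.uniform(reach + 2, base.width - reach - 2)
            cy = rng.uniform(reach + 2, top_rows - reach - 2)
            cfg = replace(
                base,
                lesion_center=(float(cx), float(cy)),
                lesion_axes=(float(a), float(b)),
                lesion_angle=float(rng.uniform(*ranges["angle"])),
                lesion_level=float(rng.uniform(*ranges["lesion_level"])),
                background_level=float(rng.uniform(*ranges["background_level"])),
                shadow=bool(rng.uniform() < shadow_fraction),
                seed=sample_seed)
        sample = generate_phantom(cfg)
        samples.append(sample)
        tb = sample.truth_box
        rows.append({
            "sample_id": f"phantom_{i:04d}",
            "seed": sample_seed,
            "normal": i in normal_idx,
            "center_x": None if cfg.lesion_center is None else cfg.lesion_center[0],
            "center_y": None if cfg.lesion_center is None else cfg.lesion_center[1],
            "axis_a": None if cfg.lesion_center is None else cfg.lesion_axes[0],
            "axis_b": None if cfg.lesion_center is None else cfg.lesion_axes[1],
            "angle": None if cfg.lesion_center is None else cfg.lesion_angle,
            "shadow": cfg.shadow,
            "box_x": None if tb is None else tb.x,
            "box_y": None if tb is None else tb.y,
            "box_w": None if tb is None else tb.w,
            "box_h": None if tb is None else tb.h,
        })
    return samples, pd.DataFrame(rows)


def write_dataset(samples: list[PhantomSample], manifest: pd.DataFrame,
                  out_dir) -> None:
    """Write images, masks, truth boxes, and the manifest to a directory."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    records = []
    for row, sample in zip(manifest.itertuples(), samples):
        usio.write_image(sample.image, out / "images" / f"{row.sample_id}.png")
        usio.write_mask(sample.mask, out / "masks" / f"{row.sample_id}.png")
        if sample.truth_box is not None:
            records.append(usio.DetectionRecord.from_box(row.sample_id,
                                                         sample.truth_box))
    usio.write_detections(records, out / "truth_boxes.json")
    manifest.to_csv(out / "manifest.csv", index=False)
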