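"""Synthetic ultrasound-like stacks and controlled tampering.

The generator emulates a B-mode ultrasound cine loop: a fan-shaped scan
sector (apex at the top centre) filled with multiplicative speckle over a
smooth anatomical phantom (elliptical inclusions of differing echogenicity
that drift slightly from frame to frame), on a near-black constant
background. This reproduces the two statistical properties the embedding
design relies on: ROI LSB planes with near-maximal entropy (speckle, hence
an essentially incompressible archive section) and RONI LSB planes that are
constant and compress to almost nothing, so the whole-frame LSB archive fits
the RONI capacity at a ~40% ROI.

Tampering emulates manual pixel edits in an image editor: constant fill,
noise, a region copied from another frame, or an LSB-only edit that corrupts
the embedded payload without visibly changing the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dicom_io import ImageStack
from .embedder import RegionSpec, WatermarkConfig

__all__ = [
    "FixtureSpec",
    "TamperSpec",
    "fan_roi_mask",
    "gen_stack",
    "tamper",
    "default_config",
]


def fan_roi_mask(
    height: int,
    width: int,
    radius_frac: float = 0.95,
    half_angle_deg: float = 35.0,
    apex_row_frac: float = 0.02,
) -> np.ndarray:
    """Fan-shaped (sector) ROI mask with the apex at the top centre.

    The defaults give roughly 40% ROI area on a 480x640 frame, matching a
    typical abdominal B-mode footprint.
    """
    rows = np.arange(height)[:, None] - apex_row_frac * height
    cols = np.arange(width)[None, :] - width / 2.0
    radius = np.hypot(rows, cols)
    angle = np.arctan2(np.abs(cols), rows)  # 0 = straight down
    return (
        (rows >= 0)
        & (radius <= radius_frac * height)
        & (angle <= np.deg2rad(half_angle_deg))
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic cine stack.

    ``speckle_mean`` is the mean ROI intensity (0–255) and
    ``speckle_variance`` its variance; the multiplicative speckle factor is
    gamma-distributed with unit mean. Identical specs generate identical
    stacks.
    """

    frame_count: int = 15
    height: int = 480
    width: int = 640
    seed: int = 7
    roi: Optional[RegionSpec] = None
    speckle_mean: float = 130.0
    speckle_variance: float = 1600.0
    background_level: int = 4

    def __post_init__(self) -> None:
        if self.frame_count < 1 or self.height < 1 or self.width < 1:
            raise ValueError("dimensions and frame count must be positive")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must be an 8-bit intensity")

    def roi_mask(self) -> np.ndarray:
        if self.roi is not None:
            mask = self.roi.roi_mask
            if mask.shape != (self.height, self.width):
                raise ValueError(
                    f"ROI mask {mask.shape} exceeds frame bounds "
                    f"({self.height}, {self.width})"
                )
            return mask
        return fan_roi_mask(self.height, self.width)


def _phantom(spec: FixtureSpec, frame_idx: int) -> np.ndarray:
    """Smooth anatomical base: background echogenicity plus two elliptical
    inclusions (one hypoechoic, one hyperechoic) that drift across frames."""
    h, w = spec.height, spec.width
    y = np.arange(h)[:, None]
    x = np.arange(w)[None, :]
    base = np.full((h, w), spec.speckle_mean, dtype=np.float64)
    drift = 6.0 * np.sin(2 * np.pi * frame_idx / max(spec.frame_count, 1))
    cy1, cx1 = 0.45 * h + drift, 0.42 * w
    cy2, cx2 = 0.62 * h, 0.58 * w + drift
    dark = ((y - cy1) / (0.14 * h)) ** 2 + ((x - cx1) / (0.10 * w)) ** 2 <= 1.0
    bright = ((y - cy2) / (0.10 * h)) ** 2 + ((x - cx2) / (0.08 * w)) ** 2 <= 1.0
    base[dark] *= 0.45
    base[bright] *= 1.35
    return base


def gen_stack(spec: FixtureSpec) -> ImageStack:
    """Generate a deterministic ultrasound-like stack from a spec."""
    mask = spec.roi_mask()
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    # gamma speckle with unit mean; shape chosen so intensity variance at the
    # mean echogenicity matches speckle_variance
    shape = max(spec.speckle_mean**2 / max(spec.speckle_variance, 1e-9), 1e-3)
    frames = np.empty((spec.frame_count, spec.height, spec.width), dtype=np.uint8)
    for i in range(spec.frame_count):
        base = _phantom(spec, i)
        speckle = rng.gamma(shape, 1.0 / shape, size=base.shape)
        frame = np.full(base.shape, float(spec.background_level))
        frame[mask] = base[mask] * speckle[mask]
        frames[i] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    return ImageStack(frames, meta={"synthetic": True, "seed": spec.seed})


def default_config(
    height: int = 480,
    width: int = 640,
    key: int = 0xC0FFEE,
    roi: Optional[RegionSpec] = None,
) -> WatermarkConfig:
    """Watermark config with the fan ROI the generator uses by default."""
    region = roi or RegionSpec(fan_roi_mask(height, width))
    return WatermarkConfig(roi=region, key=key)


@dataclass(frozen=True)
class TamperSpec:
    """A controlled forgery: which (1-based) frames to edit, where, and how.

    Modes: ``fill`` paints the region with a constant; ``noise`` replaces it
    with random intensities; ``copy`` pastes the region from another frame;
    ``lsb`` zeroes only the LSB planes (invisible, corrupts the payload).
    """

    frame_numbers: Sequence[int]
    region: tuple[int, int, int, int]  # x, y, w, h (x = column)
    mode: str = "fill"
    fill_value: int = 0
    lsb_count: int = 2
    source_frame: Optional[int] = None  # 1-based, for mode="copy"

    def __post_init__(self) -> None:
        if self.mode not in ("fill", "noise", "copy", "lsb"):
            raise ValueError(f"unknown tamper mode {self.mode!r}")
        x, y, w, h = self.region
        if w <= 0 or h <= 0 or x < 0 or y < 0:
            raise ValueError("tamper region must have positive size inside the frame")


def tamper(stack: ImageStack, spec: TamperSpec, seed: int = 0) -> ImageStack:
    """Apply the forgery; only the listed frames differ from the input."""
    x, y, w, h = spec.region
    if y + h > stack.height or x + w > stack.width:
        raise ValueError(f"tamper region {spec.region} exceeds frame bounds")
    for fn in spec.frame_numbers:
        if not 1 <= fn <= stack.frame_count:
            raise ValueError(f"frame number {fn} out of range 1..{stack.frame_count}")
    rng = np.random.Generator(np.random.PCG64(seed))
    frames = stack.frames.copy()
    for fn in spec.frame_numbers:
        i = fn - 1
        region = frames[i, y : y + h, x : x + w]
        if spec.mode == "fill":
            new = np.full_like(region, np.uint8(spec.fill_value))
            if np.array_equal(new, region):  # guarantee a visible edit
                new = region ^ np.uint8(1 << 7)
        elif spec.mode == "noise":
            new = rng.integers(0, 256, size=region.shape, dtype=np.uint8)
            if np.array_equal(new, region):
                new = region ^ np.uint8(1 << 7)
        elif spec.mode == "copy":
            src = (spec.source_frame - 1) if spec.source_frame else (i + 1) % stack.frame_count
            new = stack.frames[src, y : y + h, x : x + w].copy()
            if np.array_equal(new, region):
                new = region ^ np.uint8(1 << 7)
        else:  # lsb
            keep = np.uint8((0xFF << spec.lsb_count) & 0xFF)
            new = region & keep
            if np.array_equal(new, region):
                new = region ^ np.uint8(1)  # flip a payload bit instead
        frames[i, y : y + h, x : x + w] = new
        if np.array_equal(frames[i], stack.frames[i]):
            raise ValueError(f"tamper left frame {fn} unchanged")
    return ImageStack(frames, dict(stack.meta))
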