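"""Whole-image preprocessing for transfer-learning classifiers.

A 16-bit CLE frame is dynamically compressed to 8 bit with a percentile
rule computed over the circular field of view,

    I_8bit = 255 / (P99.5 - P0.5) * (I - P0.5),

then the maximum square inscribed in the circular field (side 2/sqrt(2) *
r = sqrt(2) * r) is cropped around the field center, replicated to three
channels and resized to the 224x224 input of an ImageNet-style network.
Fine-tuning a pretrained network is out of scope here; this module provides
the exact input chain such a classifier would consume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .io import CLEFrame


@dataclass
class EightBitImage:
    """8-bit dynamic-compressed view of a frame."""

    pixels: np.ndarray  # uint8, (H, W)
    source: str = ""


@dataclass
class SquareCrop:
    """Geometry of the maximum square inside the circular field."""

    side: int
    x0: int
    y0: int


def percentile_compress(frame: CLEFrame) -> EightBitImage:
    """Compress 16-bit intensities to 8 bit by the 0.5/99.5 percentile rule.

    Percentiles are computed over in-field pixels only; output values are
    rounded half-up and clipped to [0, 255].  A degenerate frame (equal
    percentiles) maps to all zeros with a warning.
    """
    mask = frame.field_mask()
    vals = frame.pixels[mask].astype(np.float64)
    lo = np.percentile(vals, 0.5)
    hi = np.percentile(vals, 99.5)
    if hi <= lo:
        warnings.warn("degenerate intensity range; emitting all-zero 8-bit image",
                      stacklevel=2)
        out = np.zeros(frame.pixels.shape, dtype=np.uint8)
    else:
        scaled = 255.0 / (hi - lo) * (frame.pixels.astype(np.float64) - lo)
        out = np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)
    ref = f"{frame.patient_id}/{frame.sequence_id}/{frame.frame_index}"
    return EightBitImage(pixels=out, source=ref)


def max_square_side(radius: float) -> int:
    """Side of the centered maximum square: floor(sqrt(2) * radius) px."""
    return int(math.floor(math.sqrt(2.0) * radius))


def max_square_crop(
    image: EightBitImage, field: tuple[tuple[float, float], float]
) -> np.ndarray:
    """Crop the centered maximum square from the 8-bit image.

    The side is floor(sqrt(2)*r) so the square never leaves the disc.
    """
    (cx, cy), radius = field
    side = max_square_side(radius)
    h, w = image.pixels.shape
    x0 = int(round(cx - (side - 1) / 2.0))
    y0 = int(round(cy - (side - 1) / 2.0))
    if x0 < 0 or y0 < 0 or x0 + side > w or y0 + side > h:
        raise ValueError("maximum square exceeds image bounds")
    return image.pixels[y0 : y0 + side, x0 : x0 + side].copy()


def discarded_field_fraction(radius: float, dims: tuple[int, int] | None = None) -> float:
    """Fraction of in-field pixels outside the maximum-square crop.

    Measured by pixel counting on an actual grid; analytically the fraction
    tends to 1 - 2/pi (about 36%) for the exact inscribed square.
    """
    if dims is None:
        n = int(math.ceil(2 * radius))
        dims = (n, n)
    w, h = dims
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    infield = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    side = max_square_side(radius)
    x0 = int(round(cx - (side - 1) / 2.0))
    y0 = int(round(cy - (side - 1) / 2.0))
    insquare = np.zeros_like(infield)
    insquare[max(y0, 0) : y0 + side, max(x0, 0) : x0 + side] = True
    kept = np.logical_and(infield, insquare).sum()
    return 1.0 - kept / infield.sum()


def prepare_rgb_input(
    cropped: np.ndarray, target: int = 224
) -> tuple[np.ndarray, float]:
    """Replicate a square 8-bit crop to RGB and resize to ``target`` px.

    Returns the (target, target, 3) float array in [0, 1] and the applied
    scale factor (about 0.55 for the canonical 407-px crop).
    """
    if cropped.ndim != 2 or cropped.shape[0] != cropped.shape[1]:
        raise ValueError("expected a square single-channel crop")
    side = cropped.shape[0]
    scale = target / side
    img = cropped.astype(np.float64) / 255.0
    if side != target:
        img = resize(img, (target, target), anti_aliasing=side > target,
                     preserve_range=True)
    rgb = np.repeat(img[..., None], 3, axis=2)
    return rgb, scale
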