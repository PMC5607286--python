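"""Patch probability fusion: from per-patch posteriors to an image posterior.

Each scored patch covers a closed pixel rectangle.  The patch activity map
PA marks pixels covered by at least one patch, the patch count map PC counts
covering patches (floored at 1), and the probability map PM holds, at each
covered pixel, the arithmetic mean of the posteriors of the patches covering
it.  The scalar image probability p(I) is the mean of PM over active pixels;
because overlap regions average several patches, p(I) places slightly more
weight on multiply-covered areas than a flat patch mean would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .io import CLEFrame
from .patches import Patch


@dataclass
class ScoredPatch:
    """A patch rectangle with its classifier posterior."""

    corners: tuple[int, int, int, int]  # (c1, c2, c3, c4)
    p: float


@dataclass
class FusionMaps:
    """PA / PC / PM rasters at frame resolution (arrays are (H, W))."""

    PA: np.ndarray  # bool
    PC: np.ndarray  # int, >= 1 everywhere
    PM: np.ndarray  # float in [0, 1] where PA, 0 elsewhere


@dataclass
class ImageProbability:
    """Scalar fused probability; undefined when no patch covered the frame."""

    p: float | None
    n_patches: int
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.p is not None


def area_indicator(patch: Patch | ScoredPatch, point: tuple[int, int]) -> int:
    """1 iff the point lies in the closed rectangle [c1,c2] x [c3,c4]."""
    c1, c2, c3, c4 = patch.corners
    x, y = point
    return int(c1 <= x <= c2 and c3 <= y <= c4)


def compute_fusion_maps(
    scored: list[ScoredPatch], dims: tuple[int, int]
) -> FusionMaps:
    """Accumulate the activity, count and probability maps over ``dims=(W,H)``.

    Covered pixels hold the arithmetic mean of the covering patches'
    posteriors; uncovered pixels hold PA=0, PC=1, PM=0.
    """
    w, h = dims
    cover = np.zeros((h, w), dtype=np.int64)
    wsum = np.zeros((h, w), dtype=np.float64)
    for sp in scored:
        c1, c2, c3, c4 = sp.corners
        if c1 < 0 or c3 < 0 or c2 >= w or c4 >= h:
            raise ValueError(f"patch rectangle {sp.corners} outside {w}x{h}")
        cover[c3 : c4 + 1, c1 : c2 + 1] += 1
        wsum[c3 : c4 + 1, c1 : c2 + 1] += sp.p
    pa = cover >= 1
    pc = np.maximum(1, cover)
    pm = np.where(pa, wsum / pc, 0.0)
    return FusionMaps(PA=pa, PC=pc, PM=pm)


def fuse_image_probability(
    maps: FusionMaps, n_patches: int | None = None
) -> ImageProbability:
    """Mean of PM over active pixels; undefined when PA is all zero."""
    n_active = int(maps.PA.sum())
    if n_active == 0:
        return ImageProbability(p=None, n_patches=0, reason="no valid patches")
    if n_patches is None:
        # lower bound recoverable from the maps alone: the deepest overlap
        n_patches = int(maps.PC[maps.PA].max())
    return ImageProbability(p=float(maps.PM[maps.PA].sum() / n_active), n_patches=n_patches)


def fuse_patches(
    patches: list[Patch], probabilities: list[float], dims: tuple[int, int]
) -> tuple[FusionMaps, ImageProbability]:
    """Convenience: maps plus scalar probability from patches and posteriors."""
    scored = [ScoredPatch(p.corners, float(q)) for p, q in zip(patches, probabilities)]
    maps = compute_fusion_maps(scored, dims)
    return maps, fuse_image_probability(maps, n_patches=len(patches))


def write_maps_tiff(maps: FusionMaps, path) -> None:
    """Export the PA/PC/PM rasters as a 3-page 32-bit float TIFF."""
    import tifffile

    stack = np.stack(
        [maps.PA.astype(np.float32), maps.PC.astype(np.float32),
         maps.PM.astype(np.float32)]
    )
    tifffile.imwrite(path, stack)


def write_overlay_png(frame: CLEFrame, maps: FusionMaps, path, **kwargs) -> None:
    """Render and save the color-coded overlay as PNG."""
    from PIL import Image

    Image.fromarray(render_overlay(frame, maps, **kwargs)).save(path)


def render_overlay(
    frame: CLEFrame,
    maps: FusionMaps,
    cmap: str = "coolwarm",
    alpha: float = 0.5,
) -> np.ndarray:
    """Blend a diverging colormap of PM (masked by PA) over the gray frame.

    Returns an (H, W, 3) uint8 RGB image; inactive pixels show the plain
    grayscale rendering.
    """
    if frame.pixels.shape != maps.PM.shape:
        raise ValueError("frame and fusion maps have different dimensions")
    gray = frame.pixels.astype(np.float64)
    lo, hi = gray.min(), gray.max()
    gray = (gray - lo) / (hi - lo) if hi > lo else np.zeros_like(gray)
    rgb = np.repeat(gray[..., None], 3, axis=2)
    colors = colormaps[cmap](np.clip(maps.PM, 0.0, 1.0))[..., :3]
    mask = maps.PA[..., None]
    blended = np.where(mask, (1 - alpha) * rgb + alpha * colors, rgb)
    return (np.clip(blended, 0, 1) * 255).round().astype(np.uint8)
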