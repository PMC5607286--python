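"""Patch extraction geometry for circular-field CLE frames.

Frames are optionally downscaled (the canonical pipeline runs at 0.5x), then
covered by an 80x80 grid with 50% overlap anchored at the frame center.  A
candidate patch is kept only if every one of its pixel centers lies inside
the circular field of view and its rectangle touches no annotated artifact
box.  Each kept patch carries a corner quadruple ``[c1, c2, c3, c4]`` with
``(c1, c3)`` the top-left and ``(c2, c4)`` the bottom-right pixel, 0-based
and inclusive, so ``c2 - c1 + 1`` equals the patch size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import downscale_local_mean, resize

from .io import CLEFrame

PATCH_SIZE = 80


@dataclass(eq=False)
class Patch:
    """An extracted patch with its corner quadruple in frame coordinates."""

    pixels: np.ndarray
    corners: tuple[int, int, int, int]  # (c1, c2, c3, c4): x-range, y-range
    label: str
    patient_id: str
    frame_ref: str = ""
    whitened: bool = False

    @property
    def size(self) -> int:
        return self.corners[1] - self.corners[0] + 1


@dataclass
class PatchGrid:
    """Candidate patch positions (top-left corners) for a frame."""

    patch_size: int
    stride: int
    xs: list[int]
    ys: list[int]

    @property
    def candidate_positions(self) -> list[tuple[int, int]]:
        return [(x, y) for y in self.ys for x in self.xs]


def downscale_image(frame: CLEFrame, factor: float) -> CLEFrame:
    """Anti-aliased area downscaling of a frame; geometry scales with it.

    Integer reciprocal factors (0.5, 0.25, ...) use exact block-mean (area)
    resampling; other factors fall back to anti-aliased interpolation.
    """
    if factor <= 0 or factor > 1:
        raise ValueError("downscale factor must be in (0, 1]")
    if factor == 1.0:
        return frame
    h, w = frame.pixels.shape
    inv = 1.0 / factor
    if abs(inv - round(inv)) < 1e-9 and h % round(inv) == 0 and w % round(inv) == 0:
        k = int(round(inv))
        out = downscale_local_mean(frame.pixels.astype(np.float64), (k, k))
    else:
        out_shape = (int(round(h * factor)), int(round(w * factor)))
        out = resize(
            frame.pixels.astype(np.float64),
            out_shape,
            anti_aliasing=True,
            preserve_range=True,
        )
    cx, cy = frame.field_center
    # pixel-center coordinates transform as (c + 1/2)*f - 1/2 so that the
    # inscribed disc of a full-field frame stays the inscribed disc
    return CLEFrame(
        pixels=np.clip(np.rint(out), 0, 65535).astype(np.uint16),
        patient_id=frame.patient_id,
        sequence_id=frame.sequence_id,
        frame_index=frame.frame_index,
        location=frame.location,
        label=frame.label,
        field_center=((cx + 0.5) * factor - 0.5, (cy + 0.5) * factor - 0.5),
        field_radius=frame.field_radius * factor,
        artifact_boxes=[b.scaled(factor) for b in frame.artifact_boxes],
        augmented=frame.augmented,
    )


def _axis_positions(extent: int, patch_size: int, stride: int) -> list[int]:
    center = extent - patch_size
    if center % 2 != 0:
        raise ValueError(
            f"cannot center {patch_size}px patches on extent {extent}: "
            f"extent - patch_size must be even"
        )
    center //= 2
    k_min = -(center // stride)
    k_max = (extent - patch_size - center) // stride
    return [center + stride * k for k in range(k_min, k_max + 1)]


def plan_patch_grid(
    frame_dims: tuple[int, int], patch_size: int = PATCH_SIZE, stride: int | None = None
) -> PatchGrid:
    """Plan the center-anchored overlapping grid of candidate patches.

    Per axis the top-left positions are ``(extent - patch_size)/2 + stride*k``
    for every integer ``k`` that keeps the patch inside the frame, which
    yields an odd number of positions with one patch exactly centered.
    """
    w, h = frame_dims
    if stride is None:
        stride = patch_size // 2
    if patch_size > min(w, h):
        raise ValueError("patch size exceeds frame dimensions")
    return PatchGrid(
        patch_size=patch_size,
        stride=stride,
        xs=_axis_positions(w, patch_size, stride),
        ys=_axis_positions(h, patch_size, stride),
    )


def _inside_field(
    x0: int, y0: int, size: int, center: tuple[float, float], radius: float
) -> bool:
    # Distance to the field center is maximized at one of the 4 corner pixel
    # centers of the (closed) patch rectangle.
    cx, cy = center
    r2 = radius * radius
    for x in (x0, x0 + size - 1):
        for y in (y0, y0 + size - 1):
            if (x - cx) ** 2 + (y - cy) ** 2 > r2:
                return False
    return True


def extract_patches(frame: CLEFrame, grid: PatchGrid | None = None) -> list[Patch]:
    """Extract all candidate patches inside the field and off any artifact.

    Returned patches are raw (un-whitened) float32 copies of frame pixels.
    """
    if grid is None:
        grid = plan_patch_grid(frame.pixels.shape[::-1])
    size = grid.patch_size
    h, w = frame.pixels.shape
    out: list[Patch] = []
    ref = f"{frame.patient_id}/{frame.sequence_id}/{frame.frame_index}"
    for y0 in grid.ys:
        for x0 in grid.xs:
            if x0 < 0 or y0 < 0 or x0 + size > w or y0 + size > h:
                continue
            if not _inside_field(x0, y0, size, frame.field_center, frame.field_radius):
                continue
            if any(
                b.intersects(x0, y0, x0 + size - 1, y0 + size - 1)
                for b in frame.artifact_boxes
            ):
                continue
            out.append(
                Patch(
                    pixels=frame.pixels[y0 : y0 + size, x0 : x0 + size]
                    .astype(np.float32)
                    .copy(),
                    corners=(x0, x0 + size - 1, y0, y0 + size - 1),
                    label=frame.label,
                    patient_id=frame.patient_id,
                    frame_ref=ref,
                )
            )
    return out


def save_patch_set(patches: Sequence[Patch], path) -> None:
    """Serialize patches as one array (.npz) plus a JSON provenance sidecar.

    The sidecar records corner quadruples, labels, patient ids, source-frame
    references and the whitened flag, index-aligned with the array.
    """
    import json
    from pathlib import Path as _Path

    path = _Path(path)
    stack = (
        np.stack([p.pixels for p in patches]).astype(np.float32)
        if patches
        else np.zeros((0, PATCH_SIZE, PATCH_SIZE), np.float32)
    )
    np.savez_compressed(path.with_suffix(".npz"), patches=stack)
    sidecar = [
        dict(corners=list(p.corners), label=p.label, patient_id=p.patient_id,
             frame_ref=p.frame_ref, whitened=p.whitened)
        for p in patches
    ]
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_patch_set(path) -> list[Patch]:
    """Inverse of :func:`save_patch_set`."""
    import json
    from pathlib import Path as _Path

    path = _Path(path)
    with np.load(path.with_suffix(".npz")) as data:
        stack = data["patches"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return [
        Patch(pixels=stack[i].copy(), corners=tuple(meta["corners"]),
              label=meta["label"], patient_id=meta["patient_id"],
              frame_ref=meta["frame_ref"], whitened=meta["whitened"])
        for i, meta in enumerate(sidecar)
    ]


def whiten_patch(patch: Patch) -> Patch:
    """Standard-scale a patch to zero mean and unit (population) std.

    A near-constant patch (std below 1e-8) maps to all zeros.
    """
    x = patch.pixels.astype(np.float64)
    mu = x.mean()
    sd = x.std()
    if sd < 1e-8:
        w = np.zeros_like(x, dtype=np.float32)
    else:
        w = ((x - mu) / sd).astype(np.float32)
    return replace(patch, pixels=w, whitened=True)


def rotate_frame(frame: CLEFrame, angle_deg: float) -> CLEFrame:
    """Rotate a frame about its field center (bilinear, zero fill)."""
    if angle_deg % 360.0 == 0.0:
        rotated = frame.pixels.copy()
    else:
        theta = np.deg2rad(angle_deg)
        c, s = np.cos(theta), np.sin(theta)
        cx, cy = frame.field_center
        # Inverse map: output (y, x) -> input coordinates, rotating about
        # (cy, cx) in array order.
        mat = np.array([[c, -s], [s, c]])
        offset = np.array([cy, cx]) - mat @ np.array([cy, cx])
        rotated = ndimage.affine_transform(
            frame.pixels.astype(np.float32), mat, offset=offset, order=1, cval=0.0
        )
        rotated = np.clip(np.rint(rotated), 0, 65535).astype(np.uint16)
    return CLEFrame(
        pixels=rotated,
        patient_id=frame.patient_id,
        sequence_id=frame.sequence_id,
        frame_index=frame.frame_index,
        location=frame.location,
        label=frame.label,
        field_center=frame.field_center,
        field_radius=frame.field_radius,
        artifact_boxes=[],  # boxes do not survive rotation; see augment notes
        augmented=True,
    )


def augment_rotations(
    frames: Sequence[CLEFrame],
    fold_factor: int = 2,
    rng_seed: int = 0,
    split: str = "train",
    angles: Sequence[float] | None = None,
) -> list[CLEFrame]:
    """Add ``fold_factor`` randomly rotated copies of each training frame.

    Rotated copies are tagged ``augmented=True`` and inherit label and
    patient; the originals are retained first in the returned list.  Frames
    with artifact boxes are rotated too, but their boxes are dropped and the
    copy keeps only the field mask (rotation invalidates axis-aligned
    annotations), so augmentation is skipped for annotated frames.
    """
    if split == "test":
        raise ValueError("augmented data may not be used for testing")
    if fold_factor < 0:
        raise ValueError("fold_factor must be >= 0")
    rng = np.random.default_rng(rng_seed)
    out = list(frames)
    for frame in frames:
        if frame.artifact_boxes:
            continue
        for j in range(fold_factor):
            angle = angles[j % len(angles)] if angles is not None else rng.uniform(0.0, 360.0)
            out.append(rotate_frame(frame, angle))
    return out


def balance_classes(frames: Sequence[CLEFrame], rng_seed: int = 0) -> list[CLEFrame]:
    """Equalize class counts by removing augmented majority-class frames.

    Originals are never removed; if the majority class runs out of augmented
    frames before the counts match, a warning reports the residual imbalance.
    """
    labels = {f.label for f in frames}
    if len(labels) < 2:
        raise ValueError("both classes must be present to balance")
    counts = {lab: sum(f.label == lab for f in frames) for lab in labels}
    majority = max(counts, key=counts.get)
    minority = min(counts, key=counts.get)
    excess = counts[majority] - counts[minority]
    if excess == 0:
        return list(frames)
    rng = np.random.default_rng(rng_seed)
    removable = [i for i, f in enumerate(frames) if f.label == majority and f.augmented]
    drop = set(rng.permutation(len(removable))[:excess].tolist())
    drop_idx = {removable[i] for i in drop}
    if len(removable) < excess:
        warnings.warn(
            f"could not fully balance classes: residual imbalance "
            f"{counts[majority] - len(removable)} vs {counts[minority]}",
            stacklevel=2,
        )
    return [f for i, f in enumerate(frames) if i not in drop_idx]
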