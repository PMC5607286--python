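"""Reading and validating CLE frames, field geometry and cohort manifests.

Confocal laser endomicroscopy (CLE) frames are single-channel 16-bit images
with a circular field of view.  A cohort is described by a CSV (or JSON)
manifest with one row per frame carrying patient id, anatomical location,
class label and optional rectangular artifact annotations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

LOCATIONS = ("alveolar_ridge", "inner_labium", "hard_palate", "lesion")
LABELS = ("normal", "carcinogenic")

REQUIRED_COLUMNS = (
    "patient_id",
    "sequence_id",
    "frame_index",
    "path",
    "location",
    "label",
)
OPTIONAL_COLUMNS = (
    "artifact_boxes",
    "field_center_x",
    "field_center_y",
    "field_radius",
    "height",
    "width",
)


class ManifestSchemaError(ValueError):
    """A manifest is missing a required column or violates uniqueness."""


class FrameFormatError(ValueError):
    """An image file does not match the expected CLE frame format."""


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties going away from zero (0.005 -> 0.01 at 2 dp)."""
    scale = 10.0**decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ArtifactBox:
    """Axis-aligned artifact rectangle, 0-based, inclusive on both ends."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError(f"degenerate artifact box {self}")
        if min(self.x_min, self.y_min) < 0:
            raise ValueError(f"negative artifact coordinates {self}")

    def intersects(self, x_min: int, y_min: int, x_max: int, y_max: int) -> bool:
        """True iff the closed rectangles share at least one pixel."""
        return not (
            x_max < self.x_min
            or self.x_max < x_min
            or y_max < self.y_min
            or self.y_max < y_min
        )

    def scaled(self, factor: float) -> "ArtifactBox":
        # Conservative cover: the scaled box contains the image of the
        # original closed pixel rectangle under coordinate scaling.
        return ArtifactBox(
            x_min=int(math.floor(self.x_min * factor)),
            y_min=int(math.floor(self.y_min * factor)),
            x_max=max(int(math.floor(self.x_min * factor)),
                      int(math.ceil((self.x_max + 1) * factor)) - 1),
            y_max=max(int(math.floor(self.y_min * factor)),
                      int(math.ceil((self.y_max + 1) * factor)) - 1),
        )

    def as_list(self) -> list[int]:
        return [self.x_min, self.y_min, self.x_max, self.y_max]


@dataclass(eq=False)
class CLEFrame:
    """One CLE frame: 16-bit pixels plus geometry and cohort metadata.

    ``field_center`` is in pixel-center coordinates (x, y); the default field
    of view is the disc inscribed in the frame.
    """

    pixels: np.ndarray
    patient_id: str
    location: str
    label: str
    sequence_id: str = "s0"
    frame_index: int = 0
    field_center: tuple[float, float] | None = None
    field_radius: float | None = None
    artifact_boxes: list[ArtifactBox] = field(default_factory=list)
    augmented: bool = False

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise FrameFormatError("frame pixels must be a 2-D array")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        h, w = self.pixels.shape
        if self.field_center is None:
            self.field_center = ((w - 1) / 2.0, (h - 1) / 2.0)
        if self.field_radius is None:
            self.field_radius = min(h, w) / 2.0
        if self.field_radius <= 0:
            raise ValueError("field radius must be positive")
        if self.field_radius > min(h, w):
            raise ValueError("field radius exceeds frame bounds")
        for box in self.artifact_boxes:
            if box.x_max >= w or box.y_max >= h:
                raise ValueError(f"artifact box {box} outside {w}x{h} frame")
        if self.label == "carcinogenic" and self.location != "lesion":
            warnings.warn(
                "carcinogenic frame recorded outside the lesion location",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def field_mask(self) -> np.ndarray:
        """Boolean mask of pixel centers inside the circular field of view."""
        h, w = self.pixels.shape
        cx, cy = self.field_center
        yy, xx = np.mgrid[0:h, 0:w]
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.field_radius**2


def field_geometry(frame: CLEFrame) -> tuple[tuple[float, float], float]:
    """Return ``(center, radius)`` of the circular field of view."""
    return frame.field_center, frame.field_radius


@dataclass
class DatasetManifest:
    """Per-frame cohort table with a derived patient set."""

    entries: pd.DataFrame
    root: Path | None = None

    @property
    def patients(self) -> list[str]:
        return sorted(self.entries["patient_id"].unique())

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, mask) -> "DatasetManifest":
        return DatasetManifest(self.entries[mask].reset_index(drop=True), self.root)


def _parse_boxes(raw) -> list[ArtifactBox]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return []
    if isinstance(raw, str):
        raw = json.loads(raw)
    boxes = []
    for item in raw:
        if isinstance(item, dict):
            boxes.append(ArtifactBox(**item))
        else:
            x0, y0, x1, y1 = item
            boxes.append(ArtifactBox(int(x0), int(y0), int(x1), int(y1)))
    return boxes


def load_manifest(path: str | Path) -> DatasetManifest:
    """Load and validate a cohort manifest (CSV or JSON).

    Rows are ordered deterministically by (patient_id, sequence_id,
    frame_index); that triple must be unique.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, dtype={"patient_id": str, "sequence_id": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ManifestSchemaError(f"manifest is missing required column {col!r}")
    if "artifact_boxes" not in df.columns:
        df["artifact_boxes"] = ""
    for i, row in df.iterrows():
        if row["label"] not in LABELS:
            raise ValueError(f"row {i}: unknown label {row['label']!r}")
        if row["location"] not in LOCATIONS:
            raise ValueError(f"row {i}: unknown location {row['location']!r}")
    key = df[["patient_id", "sequence_id", "frame_index"]].astype(str).agg("/".join, axis=1)
    dup = key[key.duplicated(keep=False)]
    if len(dup):
        raise ManifestSchemaError(
            "duplicate (patient, sequence, frame) keys: " + ", ".join(sorted(set(dup)))
        )
    df = df.sort_values(
        ["patient_id", "sequence_id", "frame_index"], kind="mergesort"
    ).reset_index(drop=True)
    df["parsed_boxes"] = df["artifact_boxes"].map(_parse_boxes)
    return DatasetManifest(entries=df, root=path.parent)


def read_frame(entry, root: str | Path | None = None) -> CLEFrame:
    """Read one frame referenced by a manifest row, preserving 16-bit values.

    8-bit inputs are promoted to 16 bit by an 8-bit left shift (255 -> 65280)
    with a warning; RGB inputs are rejected.
    """
    get = entry.get if hasattr(entry, "get") else entry.__getitem__
    path = Path(get("path"))
    if root is not None and not path.is_absolute():
        path = Path(root) / path
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = np.asarray(Image.open(path))
    if pixels.ndim != 2:
        raise FrameFormatError(f"{path.name}: expected a single-channel image")
    if pixels.dtype == np.uint8:
        warnings.warn(f"{path.name}: promoting 8-bit input to 16 bit", stacklevel=2)
        pixels = pixels.astype(np.uint16) << 8
    elif pixels.dtype != np.uint16:
        pixels = pixels.astype(np.uint16)

    def _opt(name):
        try:
            v = get(name)
        except (KeyError, IndexError):
            return None
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return v

    for dim, axis in (("height", 0), ("width", 1)):
        want = _opt(dim)
        if want is not None and int(want) != pixels.shape[axis]:
            raise FrameFormatError(
                f"{path.name}: manifest says {dim}={int(want)}, file has {pixels.shape[axis]}"
            )
    cx, cy, r = _opt("field_center_x"), _opt("field_center_y"), _opt("field_radius")
    boxes = _opt("parsed_boxes")
    if boxes is None:
        boxes = _parse_boxes(_opt("artifact_boxes"))
    return CLEFrame(
        pixels=pixels,
        patient_id=str(get("patient_id")),
        sequence_id=str(get("sequence_id")),
        frame_index=int(get("frame_index")),
        location=get("location"),
        label=get("label"),
        field_center=(float(cx), float(cy)) if cx is not None and cy is not None else None,
        field_radius=float(r) if r is not None else None,
        artifact_boxes=list(boxes),
    )


def write_frame(frame: CLEFrame, path: str | Path) -> None:
    """Write the frame as a 16-bit grayscale TIFF (bit-exact round trip)."""
    tifffile.imwrite(Path(path), frame.pixels.astype(np.uint16))


@dataclass
class ManifestSummary:
    """Per-(class, location) frame counts with cohort shares."""

    table: pd.DataFrame
    total: int
    mean_frames_per_patient: int


def summarize_manifest(manifest: DatasetManifest) -> ManifestSummary:
    """Tabulate frame counts per (label, location) with percentage shares.

    Percentages use round-half-up at 2 decimal places; the mean frame count
    per patient is rounded to the nearest integer.
    """
    df = manifest.entries
    if not len(df):
        raise ValueError("empty manifest")
    counts = (
        df.groupby(["label", "location"], sort=True).size().rename("n_frames").reset_index()
    )
    total = int(counts["n_frames"].sum())
    counts["percent"] = [
        round_half_up(100.0 * n / total, 2) for n in counts["n_frames"]
    ]
    mean_per_patient = int(round_half_up(total / len(manifest.patients), 0))
    return ManifestSummary(table=counts, total=total, mean_frames_per_patient=mean_per_patient)


def cohort_shares(good_counts: Sequence[int]) -> list[float]:
    """Percentage share of each stratum among retained (good) frames, 2 dp."""
    total = sum(good_counts)
    return [round_half_up(100.0 * n / total, 2) for n in good_counts]


def retention_percentage(n_total: int, n_good: int, decimals: int = 1) -> float:
    """Share of frames of a stratum that survived quality triage, in percent."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round_half_up(100.0 * n_good / n_total, decimals)


def mean_frames_per_patient(n_frames: int, n_patients: int) -> int:
    """Mean retained frame count per patient, rounded to the nearest integer."""
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    return int(round_half_up(n_frames / n_patients, 0))
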