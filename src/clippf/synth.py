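"""Synthetic CLE cohort generator.

Emulates the two visual phenotypes the frame classifier must separate:

* clinically normal mucosa — an organized, connected network of bright
  cell borders (fluorescein in the intercellular gaps) around darker cell
  interiors, built as ridges of a Voronoi-like tessellation of blue-noise
  seed points;
* carcinogenic tissue — disorganized low-coherence texture with an elevated
  bright background (fluorescein leakage) and dark elliptical cell
  clusters, with no connected ridge network.

Frames are 16-bit with a circular field of view (outside pixels zero),
organized into patients whose texture parameters are jittered so that
leave-one-patient-out folds see realistic between-patient variation.
Optional artifacts (boxed noise, motion shear bands, dark occlusions) are
recorded in the manifest exactly like clinician annotations would be.

The generator's goal is statistical control for end-to-end testing of
geometry, fusion, training and cross-validation — not photorealism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import ArtifactBox, CLEFrame, DatasetManifest, load_manifest, write_frame

NORMAL_LOCATIONS = ("alveolar_ridge", "inner_labium", "hard_palate")


@dataclass
class SyntheticConfig:
    """Cohort-level generation parameters (16-bit intensity units)."""

    n_patients: int = 6
    frames_per_patient: int = 40
    carcinogenic_fraction: float = 0.5
    image_size: int = 576
    cell_scale: float = 28.0          # mean cell diameter, px
    ridge_width: float = 2.4          # half-width of bright cell borders, px
    interior_level: float = 11000.0   # dark cell interiors
    ridge_amplitude: float = 26000.0  # border brightness above interior
    leakage_intensity: float = 24000.0  # carcinoma background level
    cluster_density: float = 0.9      # dark clusters per 100x100 px
    noise_sigma: float = 1200.0       # additive Gaussian noise
    artifact_rates: dict = field(
        default_factory=lambda: {"noise": 0.08, "motion": 0.04, "occlusion": 0.04}
    )
    per_patient_jitter: float = 0.1   # relative sd of texture params
    identical_textures: bool = False  # null dial: both classes use one texture
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if not 0 <= self.carcinogenic_fraction <= 1:
            raise ValueError("carcinogenic_fraction must be in [0, 1]")
        for k, v in self.artifact_rates.items():
            if not 0 <= v <= 1:
                raise ValueError(f"artifact rate {k} outside [0, 1]")


@dataclass
class PatientParams:
    """Per-patient jittered texture parameters."""

    cell_scale: float
    ridge_width: float
    interior_level: float
    ridge_amplitude: float
    leakage_intensity: float
    cluster_density: float
    noise_sigma: float


def draw_patient_params(config: SyntheticConfig, rng: np.random.Generator) -> PatientParams:
    def jit(v, lo=0.05):
        return float(max(lo * v, v * (1.0 + config.per_patient_jitter * rng.standard_normal())))

    return PatientParams(
        cell_scale=jit(config.cell_scale),
        ridge_width=jit(config.ridge_width),
        interior_level=jit(config.interior_level),
        ridge_amplitude=jit(config.ridge_amplitude),
        leakage_intensity=jit(config.leakage_intensity),
        cluster_density=jit(config.cluster_density),
        noise_sigma=float(max(0.0, config.noise_sigma * (1.0 + config.per_patient_jitter * rng.standard_normal())))
        if config.noise_sigma > 0
        else 0.0,
    )


def _field_mask(size: int) -> np.ndarray:
    c = (size - 1) / 2.0
    r = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - c) ** 2 + (yy - c) ** 2 <= r * r


def _blue_noise_seeds(size: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid approximation of Poisson-disc seed points."""
    n = int(math.ceil(size / spacing)) + 2
    gy, gx = np.mgrid[0:n, 0:n].astype(np.float64)
    jitter = rng.uniform(-0.38, 0.38, size=(2, n, n))
    xs = (gx - 0.5 + jitter[0]) * spacing
    ys = (gy - 0.5 + jitter[1]) * spacing
    return np.stack([xs.ravel(), ys.ravel()], axis=1)


def _finalize(texture: np.ndarray, noise_sigma: float, size: int,
              rng: np.random.Generator) -> np.ndarray:
    if noise_sigma > 0:
        texture = texture + rng.normal(0.0, noise_sigma, texture.shape)
    texture[~_field_mask(size)] = 0.0
    return np.clip(np.rint(texture), 0, 65535).astype(np.uint16)


def synth_normal_texture(size: int, params: PatientParams,
                         rng: np.random.Generator) -> np.ndarray:
    """Bright connected cell-border network over dark interiors (float)."""
    seeds = _blue_noise_seeds(size, params.cell_scale, rng)
    tree = cKDTree(seeds)
    yy, xx = np.mgrid[0:size, 0:size]
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(np.float64)
    d, _ = tree.query(pts, k=2)
    gap = (d[:, 1] - d[:, 0]).reshape(size, size)
    # gap ~ 0 on Voronoi boundaries; soft ridge profile
    ridge = np.exp(-0.5 * (gap / params.ridge_width) ** 2)
    tex = params.interior_level + params.ridge_amplitude * ridge
    return ndimage.gaussian_filter(tex, 1.0)


def synth_carcinoma_texture(size: int, params: PatientParams,
                            rng: np.random.Generator) -> np.ndarray:
    """Disorganized blob texture, bright leakage background, dark clusters."""
    blobs = ndimage.gaussian_filter(rng.standard_normal((size, size)),
                                    params.cell_scale / 2.5)
    blobs = blobs / (blobs.std() + 1e-12)
    tex = params.leakage_intensity + 5000.0 * blobs
    n_clusters = int(round(params.cluster_density * (size / 100.0) ** 2))
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_clusters):
        cx, cy = rng.uniform(0, size, 2)
        a = rng.uniform(0.5, 1.4) * params.cell_scale
        b = rng.uniform(0.5, 1.4) * params.cell_scale
        theta = rng.uniform(0, np.pi)
        c, s = np.cos(theta), np.sin(theta)
        u = (xx - cx) * c + (yy - cy) * s
        v = -(xx - cx) * s + (yy - cy) * c
        dist2 = (u / a) ** 2 + (v / b) ** 2
        soft = np.exp(-0.5 * np.maximum(dist2 - 1.0, 0.0) * 8.0)
        soft[dist2 <= 1.0] = 1.0
        tex = tex * (1 - soft) + soft * rng.uniform(3000.0, 6000.0)
    return ndimage.gaussian_filter(tex, 1.0)


def synth_normal_frame(config: SyntheticConfig, params: PatientParams,
                       rng: np.random.Generator, **meta) -> CLEFrame:
    """One clinically-normal frame: ridge network, noise, circular mask."""
    tex = synth_normal_texture(config.image_size, params, rng)
    pixels = _finalize(tex, params.noise_sigma, config.image_size, rng)
    meta.setdefault("location", "alveolar_ridge")
    return CLEFrame(pixels=pixels, label="normal", **meta)


def synth_carcinoma_frame(config: SyntheticConfig, params: PatientParams,
                          rng: np.random.Generator, **meta) -> CLEFrame:
    """One carcinogenic frame: leakage background and dark cell clusters."""
    if config.identical_textures:
        tex = synth_normal_texture(config.image_size, params, rng)
    else:
        tex = synth_carcinoma_texture(config.image_size, params, rng)
    pixels = _finalize(tex, params.noise_sigma, config.image_size, rng)
    meta.setdefault("location", "lesion")
    return CLEFrame(pixels=pixels, label="carcinogenic", **meta)


def inject_artifact(
    frame: CLEFrame, kind: str, rng: np.random.Generator,
    whole_frame: bool = False,
) -> tuple[CLEFrame, ArtifactBox | None]:
    """Corrupt a frame with an annotated artifact.

    ``noise`` degrades the SNR in a random rectangle (or the whole frame
    when ``whole_frame`` is set, in which case no box is returned and the
    frame should be excluded from recognition, mirroring quality triage);
    ``motion`` applies a progressive row shear inside a band; ``occlusion``
    stamps a dark blob.  The returned box is the clinician-style rectangle
    annotation to record in the manifest.
    """
    h, w = frame.pixels.shape
    px = frame.pixels.astype(np.float64)
    if kind == "noise":
        if whole_frame:
            px = px + rng.normal(0, 12000.0, px.shape)
            out = replace(frame, pixels=np.clip(np.rint(px), 0, 65535).astype(np.uint16))
            out.pixels[~frame.field_mask()] = 0
            return out, None
        bw, bh = int(rng.integers(80, 200)), int(rng.integers(80, 200))
        x0 = int(rng.integers(0, w - bw))
        y0 = int(rng.integers(0, h - bh))
        px[y0 : y0 + bh, x0 : x0 + bw] += rng.normal(0, 12000.0, (bh, bw))
        box = ArtifactBox(x0, y0, x0 + bw - 1, y0 + bh - 1)
    elif kind == "motion":
        bh = int(rng.integers(40, 120))
        y0 = int(rng.integers(0, h - bh))
        max_shift = int(rng.integers(8, 40))
        for i in range(bh):
            shift = int(round(max_shift * (i + 1) / bh))
            px[y0 + i] = np.roll(px[y0 + i], shift)
        box = ArtifactBox(0, y0, w - 1, y0 + bh - 1)
    elif kind == "occlusion":
        r = int(rng.integers(40, 110))
        cx = int(rng.integers(r, w - r))
        cy = int(rng.integers(r, h - r))
        yy, xx = np.mgrid[0:h, 0:w]
        blob = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        px[blob] = rng.uniform(500.0, 2000.0)
        box = ArtifactBox(cx - r, cy - r, cx + r, cy + r)
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")
    pixels = np.clip(np.rint(px), 0, 65535).astype(np.uint16)
    pixels[~frame.field_mask()] = 0
    out = replace(frame, pixels=pixels,
                  artifact_boxes=frame.artifact_boxes + [box])
    return out, box


def generate_cohort(
    config: SyntheticConfig, outdir: str | Path
) -> DatasetManifest:
    """Write a patient-structured cohort (16-bit TIFFs + CSV manifest).

    Every patient carries a lesion: a ``carcinogenic_fraction`` share of
    their frames is carcinogenic (location ``lesion``), the rest cycles
    through the three presumably-normal recording sites, so LOPO folds mix
    both classes as in a clinical study.  Fully determined by ``rng_seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    rows = []
    for p in range(config.n_patients):
        patient = f"p{p:02d}"
        params = draw_patient_params(config, rng)
        n_carc = int(round(config.carcinogenic_fraction * config.frames_per_patient))
        for k in range(config.frames_per_patient):
            carc = k < n_carc
            meta = dict(patient_id=patient, sequence_id="s0", frame_index=k)
            if carc:
                frame = synth_carcinoma_frame(config, params, rng, **meta)
            else:
                loc = NORMAL_LOCATIONS[k % len(NORMAL_LOCATIONS)]
                frame = synth_normal_frame(config, params, rng, location=loc, **meta)
            boxes = []
            for kind, rate in config.artifact_rates.items():
                if rng.random() < rate:
                    frame, box = inject_artifact(frame, kind, rng)
                    if box is not None:
                        boxes.append(box)
                    break  # at most one artifact per frame
            rel = f"{patient}_f{k:03d}.tiff"
            write_frame(frame, outdir / rel)
            rows.append(
                dict(
                    patient_id=patient,
                    sequence_id="s0",
                    frame_index=k,
                    path=rel,
                    location=frame.location,
                    label=frame.label,
                    artifact_boxes=json.dumps([b.as_list() for b in boxes]),
                )
            )
    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return load_manifest(manifest_path)
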