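"""Texture-feature baselines: multiscale LBP and GLCM statistics with a
random-forest image classifier.

Per patch, either (a) rotation-invariant uniform (riu2) local binary
pattern histograms at radii 1/3/5 with 8/16/24 neighbors, or (b) Haralick
and Baraldi-style statistics of 16-level gray-level co-occurrence matrices
averaged over the four unit offsets.  Image-level feature vectors are the
elementwise mean and population standard deviation of the per-patch vectors
over all kept patches of the image; a 500-tree random forest scores images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix, local_binary_pattern
from sklearn.ensemble import RandomForestClassifier

from .patches import Patch


@dataclass(frozen=True)
class LBPConfig:
    radii: tuple[int, ...] = (1, 3, 5)
    neighbors: tuple[int, ...] = (8, 16, 24)

    def __post_init__(self):
        if len(self.radii) != len(self.neighbors):
            raise ValueError("radii and neighbors must pair up")

    @property
    def n_features(self) -> int:
        # riu2 histogram over P neighbors has P + 2 bins
        return sum(p + 2 for p in self.neighbors)


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 16
    distances: tuple[int, ...] = (1,)
    angles: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("need at least 2 gray levels")


GLCM_FEATURE_NAMES = (
    "mean",
    "variance",
    "correlation",
    "contrast",
    "dissimilarity",
    "homogeneity",
    "energy",
    "entropy",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
)


@dataclass
class ImageFeatureVector:
    """Mean+std aggregate of per-patch features for one image."""

    values: np.ndarray
    label: str
    patient_id: str
    frame_ref: str = ""


def lbp_patch_histogram(patch: Patch, config: LBPConfig = LBPConfig()) -> np.ndarray:
    """Concatenated normalized riu2 histograms over the configured scales.

    Codes are taken from the interior of the patch (a margin of one radius
    is dropped per scale) so no out-of-patch neighbor is ever sampled.
    Length 10 + 18 + 26 = 54 at the default configuration.
    """
    img = np.rint(patch.pixels).astype(np.int64)  # ordinal codes; integer grid
    out = []
    for radius, neigh in zip(config.radii, config.neighbors):
        if min(img.shape) < 2 * radius + 1:
            raise ValueError(
                f"patch {img.shape} too small for LBP radius {radius}"
            )
        codes = local_binary_pattern(img, P=neigh, R=radius, method="uniform")
        core = codes[radius:-radius, radius:-radius] if radius else codes
        hist = np.bincount(core.astype(int).ravel(), minlength=neigh + 2)
        out.append(hist / hist.sum())
    return np.concatenate(out)


def quantize_patch(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Linear binning of the patch's own min-max range into ``levels`` bins."""
    x = pixels.astype(np.float64)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return np.zeros(x.shape, dtype=np.uint8)
    q = np.floor((x - lo) / (hi - lo) * levels)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def _glcm_stats(P: np.ndarray) -> np.ndarray:
    """Feature panel from one normalized symmetric co-occurrence matrix."""
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    px = P.sum(axis=1)
    mu = float((np.arange(L) * px).sum())
    var = float(((np.arange(L) - mu) ** 2 * px).sum())
    if var > 1e-12:
        corr = float((((i - mu) * (j - mu) * P).sum()) / var)
    else:
        corr = 0.0  # single-level patch: correlation defined as 0
    contrast = float(((i - j) ** 2 * P).sum())
    dissim = float((np.abs(i - j) * P).sum())
    homog = float((P / (1.0 + (i - j) ** 2)).sum())
    energy = float((P**2).sum())  # angular second moment
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())

    # sum / difference distributions p_{x+y}, p_{|x-y|}
    ks = np.arange(2 * L - 1)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (i + j).ravel(), P.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(i - j).ravel(), P.ravel())
    sum_avg = float((ks * p_sum).sum())
    sum_var = float(((ks - sum_avg) ** 2 * p_sum).sum())
    nzs = p_sum[p_sum > 0]
    sum_ent = float(-(nzs * np.log2(nzs)).sum())
    kd = np.arange(L)
    diff_mean = float((kd * p_diff).sum())
    diff_var = float(((kd - diff_mean) ** 2 * p_diff).sum())
    nzd = p_diff[p_diff > 0]
    diff_ent = float(-(nzd * np.log2(nzd)).sum())

    return np.array(
        [mu, var, corr, contrast, dissim, homog, energy, entropy,
         sum_avg, sum_var, sum_ent, diff_var, diff_ent]
    )


def glcm_features(patch: Patch, config: GLCMConfig = GLCMConfig()) -> np.ndarray:
    """Haralick/Baraldi statistics averaged over the configured offsets.

    The patch is quantized to ``config.levels`` gray levels over its own
    intensity range; matrices are symmetric and normalized.
    """
    q = quantize_patch(patch.pixels, config.levels)
    glcm = graycomatrix(
        q,
        distances=list(config.distances),
        angles=list(config.angles),
        levels=config.levels,
        symmetric=True,
        normed=True,
    )
    feats = []
    for d in range(glcm.shape[2]):
        for a in range(glcm.shape[3]):
            feats.append(_glcm_stats(glcm[:, :, d, a]))
    return np.mean(feats, axis=0)


def aggregate_image_features(per_patch: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean then population std over patches, concatenated."""
    if not per_patch:
        raise ValueError("no valid patches")
    stack = np.stack(per_patch)
    return np.concatenate([stack.mean(axis=0), stack.std(axis=0)])


def image_feature_vector(
    patches: list[Patch],
    kind: str,
    lbp_config: LBPConfig = LBPConfig(),
    glcm_config: GLCMConfig = GLCMConfig(),
) -> ImageFeatureVector:
    """Per-image mean+std aggregate of LBP or GLCM patch features.

    Features are computed on raw (un-whitened) patch intensities.
    """
    if not patches:
        raise ValueError("no valid patches")
    if kind == "lbp":
        per_patch = [lbp_patch_histogram(p, lbp_config) for p in patches]
    elif kind == "glcm":
        per_patch = [glcm_features(p, glcm_config) for p in patches]
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    p0 = patches[0]
    return ImageFeatureVector(
        values=aggregate_image_features(per_patch),
        label=p0.label,
        patient_id=p0.patient_id,
        frame_ref=p0.frame_ref,
    )


def feature_names(kind: str, lbp_config: LBPConfig = LBPConfig(),
                  glcm_config: GLCMConfig = GLCMConfig()) -> list[str]:
    """Column names for an image feature vector (means block then stds)."""
    if kind == "lbp":
        per_patch = [
            f"lbp_r{r}_p{p}_bin{i}"
            for r, p in zip(lbp_config.radii, lbp_config.neighbors)
            for i in range(p + 2)
        ]
    elif kind == "glcm":
        per_patch = [f"glcm_{name}" for name in GLCM_FEATURE_NAMES]
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    return [f"mean_{n}" for n in per_patch] + [f"std_{n}" for n in per_patch]


def write_feature_csv(vectors: list[ImageFeatureVector], kind: str, path) -> None:
    """Export image feature vectors as CSV with one named column per feature."""
    import pandas as pd

    names = feature_names(kind)
    df = pd.DataFrame([v.values for v in vectors], columns=names)
    df.insert(0, "frame_ref", [v.frame_ref for v in vectors])
    df.insert(1, "patient_id", [v.patient_id for v in vectors])
    df.insert(2, "label", [v.label for v in vectors])
    df.to_csv(path, index=False)


def rf_classify(
    train: list[ImageFeatureVector],
    test: list[ImageFeatureVector],
    n_trees: int = 500,
    rng_seed: int = 0,
) -> np.ndarray:
    """Random-forest posterior for class carcinogenic on each test image."""
    lengths = {len(v.values) for v in train} | {len(v.values) for v in test}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent feature lengths {sorted(lengths)}")
    X = np.stack([v.values for v in train])
    y = np.array([1 if v.label == "carcinogenic" else 0 for v in train])
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=rng_seed, n_jobs=1)
    rf.fit(X, y)
    Xt = np.stack([v.values for v in test])
    proba = rf.predict_proba(Xt)
    return proba[:, list(rf.classes_).index(1)]
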