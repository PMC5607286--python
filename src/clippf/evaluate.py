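"""Leave-one-patient-out evaluation with concatenated predictions.

Every fold holds out all frames of one patient; augmentation and class
balancing touch the training split only.  Per-frame probabilities from all
folds are concatenated into a single vector before any metric is computed —
per-patient class shares vary so strongly that fold-wise accuracies would
mostly reflect each patient's label mix rather than classifier skill.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from . import fusion as fusion_mod
from .cnn import NetSpec, TrainConfig, predict_patch_probabilities, train_patch_classifier
from .io import CLEFrame, DatasetManifest, read_frame
from .patches import (
    augment_rotations,
    balance_classes,
    downscale_image,
    extract_patches,
    whiten_patch,
)
from .textures import ImageFeatureVector, image_feature_vector, rf_classify

METHODS = ("ppf_cnn", "rf_lbp", "rf_glcm")


@dataclass
class FoldAssignment:
    """One LOPO fold: the held-out patient and the frame index split."""

    held_out_patient: str
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class CVConfig:
    """Knobs of a cross-validation run.

    ``max_train_frames`` / ``max_train_patches`` stratified-subsample the
    training split per fold to keep desk-scale runs fast; ``None`` uses
    everything.
    """

    patch_scale: float = 0.5
    augment_fold: int = 2
    balance: bool = True
    epochs: int = 60
    batch_size: int = 256
    learning_rate: float = 0.001
    n_trees: int = 500
    threshold: float = 0.5
    max_train_frames: int | None = None
    max_train_patches: int | None = None
    rng_seed: int = 0


@dataclass
class CVReport:
    """Concatenated per-image predictions and summary metrics."""

    probabilities: np.ndarray
    labels: np.ndarray
    patients: list[str]
    roc: list[tuple[float, float]]
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    n_undefined: int
    fold_sizes: dict[str, int] = field(default_factory=dict)


def make_lopo_folds(manifest: DatasetManifest) -> list[FoldAssignment]:
    """One fold per patient, ordered by patient id; folds partition frames."""
    patients = manifest.patients
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")
    pid = manifest.entries["patient_id"].to_numpy()
    folds = []
    for patient in patients:
        test = np.flatnonzero(pid == patient)
        train = np.flatnonzero(pid != patient)
        folds.append(FoldAssignment(patient, train_idx=train, test_idx=test))
    return folds


def roc_auc(scores: Sequence[float], labels: Sequence[int]):
    """ROC points by threshold sweep and trapezoidal AUC.

    Ties in scores produce simultaneous threshold crossings (diagonal ROC
    segments), which is exactly the Mann-Whitney tie convention.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, _ = _roc_curve(labels, np.asarray(scores, dtype=float))
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


def classification_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with carcinogenic as positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    n = len(labels)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return (tp + tn) / n, sens, spec


def fold_averaged_accuracy(
    scores, labels, patients, threshold: float = 0.5
) -> float:
    """Mean of per-patient accuracies (the protocol deliberately NOT used)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    patients = np.asarray(patients)
    accs = []
    for p in np.unique(patients):
        m = patients == p
        accs.append(float(np.mean((scores[m] >= threshold) == (labels[m] == 1))))
    return float(np.mean(accs))


class _FrameStore:
    """Reads frames once and caches downscaled patch extractions."""

    def __init__(self, manifest: DatasetManifest):
        self.manifest = manifest
        self._frames: dict[int, CLEFrame] = {}
        self._patches: dict[tuple[int, float], list] = {}
        self._features: dict[tuple[int, float, str], ImageFeatureVector | None] = {}

    def frame(self, i: int) -> CLEFrame:
        if i not in self._frames:
            entry = self.manifest.entries.iloc[i]
            self._frames[i] = read_frame(entry, root=self.manifest.root)
        return self._frames[i]

    def patches(self, i: int, scale: float) -> list:
        key = (i, scale)
        if key not in self._patches:
            frame = downscale_image(self.frame(i), scale)
            self._patches[key] = extract_patches(frame)
        return self._patches[key]

    def features(self, i: int, scale: float, kind: str):
        key = (i, scale, kind)
        if key not in self._features:
            patches = self.patches(i, scale)
            self._features[key] = (
                image_feature_vector(patches, kind) if patches else None
            )
        return self._features[key]


def ppf_score_frame(net, frame: CLEFrame, scale: float = 0.5):
    """Score one frame with the patch CNN and fuse to maps + p(I)."""
    small = downscale_image(frame, scale)
    patches = extract_patches(small)
    whitened = [whiten_patch(p) for p in patches]
    probs = predict_patch_probabilities(net, whitened)
    h, w = small.pixels.shape
    return fusion_mod.fuse_patches(patches, probs, (w, h))


def _subsample(idx: np.ndarray, labels: np.ndarray, cap: int, rng) -> np.ndarray:
    """Stratified random subsample of ``idx`` keeping the class mix."""
    if cap is None or len(idx) <= cap:
        return idx
    keep = []
    for lab in np.unique(labels):
        members = idx[labels == lab]
        want = max(1, int(round(cap * len(members) / len(idx))))
        keep.append(rng.choice(members, size=min(want, len(members)), replace=False))
    return np.sort(np.concatenate(keep))


def _train_patch_pool(store, train_idx, config: CVConfig, fold_seed: int):
    """Assemble (possibly augmented, balanced, capped) whitened patches."""
    entries = store.manifest.entries
    labels = entries["label"].to_numpy()
    rng = np.random.default_rng(fold_seed)
    idx = _subsample(
        train_idx, (labels[train_idx] == "carcinogenic").astype(int),
        config.max_train_frames, rng,
    )
    frames = [store.frame(i) for i in idx]
    for f in frames:
        if f.augmented:
            raise RuntimeError("augmented frame found among stored originals")
    if config.augment_fold > 0:
        frames = augment_rotations(frames, config.augment_fold, rng_seed=fold_seed)
        if config.balance:
            frames = balance_classes(frames, rng_seed=fold_seed + 1)
    pool = []
    for k, f in enumerate(frames):
        if not f.augmented and k < len(idx):
            patches = store.patches(idx[k], config.patch_scale)
        else:
            patches = extract_patches(downscale_image(f, config.patch_scale))
        pool.extend(whiten_patch(p) for p in patches)
    if config.max_train_patches is not None and len(pool) > config.max_train_patches:
        lab = np.array([1 if p.label == "carcinogenic" else 0 for p in pool])
        sel = _subsample(np.arange(len(pool)), lab, config.max_train_patches, rng)
        pool = [pool[i] for i in sel]
    return pool


def run_cross_validation(
    manifest: DatasetManifest,
    method: str,
    config: CVConfig = CVConfig(),
    net_spec: NetSpec | None = None,
) -> CVReport:
    """Run LOPO cross-validation with one of the configured methods.

    ``method`` is one of ``ppf_cnn`` (patch CNN + probability fusion),
    ``rf_lbp`` or ``rf_glcm`` (texture features + random forest).  Models
    are trained from scratch in every fold; per-frame probabilities are
    concatenated across folds before ROC/AUC and threshold metrics.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    store = _FrameStore(manifest)
    folds = make_lopo_folds(manifest)
    entries = manifest.entries
    labels_str = entries["label"].to_numpy()

    probs: list[float] = []
    labels: list[int] = []
    patients: list[str] = []
    n_undefined = 0
    fold_sizes = {}

    for fold_no, fold in enumerate(folds):
        fold_seed = int((config.rng_seed + 1009 * (fold_no + 1)) % (2**31 - 1))
        for i in fold.test_idx:
            if store.frame(i).augmented:
                raise RuntimeError("augmented frame in a test fold")
        if method == "ppf_cnn":
            pool = _train_patch_pool(store, fold.train_idx, config, fold_seed)
            fold_sizes[fold.held_out_patient] = len(pool)
            net, _ = train_patch_classifier(
                pool,
                TrainConfig(
                    learning_rate=config.learning_rate,
                    max_epochs=config.epochs,
                    batch_size=config.batch_size,
                    rng_seed=fold_seed,
                ),
                spec=net_spec or NetSpec(),
            )
            for i in fold.test_idx:
                patches = store.patches(i, config.patch_scale)
                if not patches:
                    n_undefined += 1
                    continue
                whitened = [whiten_patch(p) for p in patches]
                pp = predict_patch_probabilities(net, whitened)
                frame_dims = downscale_image(store.frame(i), config.patch_scale).pixels.shape
                _, image_p = fusion_mod.fuse_patches(
                    patches, pp, (frame_dims[1], frame_dims[0])
                )
                probs.append(image_p.p)
                labels.append(1 if labels_str[i] == "carcinogenic" else 0)
                patients.append(fold.held_out_patient)
        else:
            kind = "lbp" if method == "rf_lbp" else "glcm"
            train_vecs = [
                v
                for i in fold.train_idx
                if (v := store.features(i, config.patch_scale, kind)) is not None
            ]
            test_pairs = [
                (i, v)
                for i in fold.test_idx
                if (v := store.features(i, config.patch_scale, kind)) is not None
            ]
            n_undefined += len(fold.test_idx) - len(test_pairs)
            fold_sizes[fold.held_out_patient] = len(train_vecs)
            if not test_pairs:
                continue
            p = rf_classify(
                train_vecs,
                [v for _, v in test_pairs],
                n_trees=config.n_trees,
                rng_seed=fold_seed,
            )
            for (i, _), q in zip(test_pairs, p):
                probs.append(float(q))
                labels.append(1 if labels_str[i] == "carcinogenic" else 0)
                patients.append(fold.held_out_patient)

    roc, auc_value = roc_auc(probs, labels)
    acc, sens, spec = classification_metrics(probs, labels, config.threshold)
    return CVReport(
        probabilities=np.asarray(probs),
        labels=np.asarray(labels),
        patients=patients,
        roc=roc,
        auc=auc_value,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        threshold=config.threshold,
        n_undefined=n_undefined,
        fold_sizes=fold_sizes,
    )
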