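"""Shared fixtures: synthetic cohorts and (expensive) cross-validation runs.

The cross-validation reports are session-scoped so the end-to-end pipeline
is trained exactly once per configuration and inspected by several tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from clippf import CLEFrame, SyntheticConfig, generate_cohort
from clippf.evaluate import CVConfig, run_cross_validation

# Desk-scale training budget: stratified caps keep each fold's training pool
# small enough for the from-scratch numpy CNN while leaving the texture
# separation of the generator easily learnable.
PPF_CV = dict(
    epochs=4, batch_size=128, max_train_frames=30, max_train_patches=600
)


def make_frame(
    pixels, label="normal", location=None, patient="p0", **kw
) -> CLEFrame:
    if location is None:
        location = "lesion" if label == "carcinogenic" else "alveolar_ridge"
    return CLEFrame(
        pixels=np.asarray(pixels, dtype=np.uint16),
        patient_id=patient,
        location=location,
        label=label,
        **kw,
    )


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """6 patients x 40 frames at the generator's default settings."""
    cfg = SyntheticConfig(rng_seed=11)
    out = tmp_path_factory.mktemp("cohort_default")
    return cfg, generate_cohort(cfg, out)


@pytest.fixture(scope="session")
def separable_cohort(tmp_path_factory):
    """Noise-free, jitter-free cohort: the fully separable setting."""
    cfg = SyntheticConfig(
        n_patients=6,
        frames_per_patient=20,
        noise_sigma=0.0,
        per_patient_jitter=0.0,
        artifact_rates={},
        rng_seed=13,
    )
    out = tmp_path_factory.mktemp("cohort_separable")
    return cfg, generate_cohort(cfg, out)


@pytest.fixture(scope="session")
def ppf_default_report(default_cohort):
    """LOPO patch-probability-fusion run on the default cohort."""
    _, manifest = default_cohort
    return run_cross_validation(
        manifest, "ppf_cnn", CVConfig(rng_seed=17, **PPF_CV)
    )


@pytest.fixture(scope="session")
def rf_lbp_report(default_cohort):
    _, manifest = default_cohort
    return run_cross_validation(manifest, "rf_lbp", CVConfig(rng_seed=17))


@pytest.fixture(scope="session")
def rf_glcm_report(default_cohort):
    _, manifest = default_cohort
    return run_cross_validation(manifest, "rf_glcm", CVConfig(rng_seed=17))


@pytest.fixture(scope="session")
def ppf_separable_report(separable_cohort):
    _, manifest = separable_cohort
    return run_cross_validation(
        manifest, "ppf_cnn",
        CVConfig(rng_seed=19, epochs=3, batch_size=128,
                 max_train_frames=24, max_train_patches=450),
    )


@pytest.fixture(scope="session")
def ppf_shuffled_report(separable_cohort):
    """Null run: frame labels randomly permuted across the cohort."""
    _, manifest = separable_cohort
    entries = manifest.entries.copy()
    rng = np.random.default_rng(23)
    perm = rng.permutation(len(entries))
    entries["label"] = entries["label"].to_numpy()[perm]
    # keep location consistent with the permuted label to satisfy validation
    entries["location"] = np.where(
        entries["label"] == "carcinogenic", "lesion", "alveolar_ridge"
    )
    shuffled = type(manifest)(entries, manifest.root)
    return run_cross_validation(
        shuffled, "ppf_cnn",
        CVConfig(rng_seed=29, epochs=3, batch_size=128,
                 max_train_frames=24, max_train_patches=450),
    )
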