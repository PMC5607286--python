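# Methods

## Problem and model

`clippf` classifies single frames of probe-based confocal laser
endomicroscopy (CLE) of the oral mucosa as *clinically normal* or
*carcinogenic*. CLE frames are 16-bit grayscale images (576×576 px here)
with a circular field of view; healthy epithelium shows an organized network
of bright cell borders (fluorescein in intercellular gaps), while carcinoma
shows disorganized texture, diffuse bright background (fluorescein leakage)
and dark cell clusters.

The core method is **patch probability fusion (ppf)**:

1. The frame is downscaled 0.5× (area resampling; reduces noise and lets an
   80 px patch span more cell structure) and covered with 80×80 patches at
   50% overlap on a grid anchored at the frame center. A candidate patch is
   kept only if all of its pixel centers fall inside the circular field and
   its rectangle intersects no annotated artifact box. On a full-field
   288×288 frame this keeps 21 of 25 candidates (the 4 corner patches fall
   outside the disc).
2. Each kept patch is whitened (zero mean, unit population std over its
   6,400 pixels; a constant patch maps to zeros) and scored by a small
   LeNet-style CNN with a softmax posterior p(P) for class carcinogenic.
3. Per-pixel fusion: with the area indicator A of each patch rectangle
   (closed intervals), the patch activity map PA marks covered pixels, the
   patch count map PC = max(1, ΣA) counts covering patches, and the
   probability map PM holds the mean posterior of the covering patches.
   The image probability p(I) = Σ PM / Σ PA is the mean of PM over active
   pixels; because overlaps average several patches, multiply-covered areas
   carry slightly more weight than in a flat mean over patches.

### Patch-grid construction

"Centered around the middle of the image" is realized as a center-anchored
odd grid: per axis, top-left positions (extent − 80)/2 + 40·k for all
integers k keeping the patch inside the frame. This is the unique natural
reading that reproduces the published count of 21 patches at 288×288; a
corner-anchored 6×6 tiling would give 16 after field masking. The field
test uses pixel centers (0-based, the disc inscribed by default, center
((W−1)/2, (H−1)/2), radius W/2), which excludes exactly the corner patches.

### The patch classifier

Architecture: conv 64@5×5 (valid) → ReLU → maxpool 3×3 stride 3 → conv
32@5×5 (valid) → ReLU → maxpool 3×3 stride 3 → flatten (1,568) → dense 32 →
ReLU → dropout → dense 2 → softmax. Spatial trace 80→76→25→21→7. Valid
convolutions, non-overlapping 3×3 pooling and a 32-unit dense layer are the
unique member of this family with exactly 103,170 trainable parameters
(1,664 + 51,232 + 50,208 + 66), which fixes the unstated padding, pool
stride and dense width. ReLU activations and dropout 0.5 are the
conventional defaults for this architecture family and are configurable.

The network is implemented directly on numpy: convolutions as im2col /
shifted-block GEMMs through BLAS, max-pooling as small numba kernels with
argmax caching, explicit backpropagation (verified against central finite
differences in the test suite) and a hand-written Adam optimizer
(lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-8), minimizing cross-entropy. Large
per-batch buffers are reused across steps; on a single CPU core a training
step costs ~8 ms per patch. All randomness (initialization, shuffling,
dropout) derives from one integer seed, so a run is bit-reproducible on one
thread.

Training defaults: batch 256 (reduced in the test suite), up to 60 epochs
with early stopping when the epoch training loss has not improved by 1e-4
for 8 epochs.

### Augmentation and balancing

CLE frames have no natural orientation, so each training frame receives
`fold_factor` (default 2) copies rotated by uniform random angles about the
field center (bilinear, zero fill outside the source). Rotated copies are
tagged `augmented` and are refused in test splits. Class balance is then
restored by removing randomly chosen augmented frames of the majority class
only — originals are never dropped; if augmented frames run out, the
residual imbalance is reported as a warning. Frames carrying artifact boxes
are not rotated (an axis-aligned rectangle annotation does not survive
rotation); they contribute their original patches only. Rotation happens
before downscaling; the order is configurable.

### Texture baselines

Two classical pipelines serve as comparison methods, each at 1.0× and 0.5×
scale:

* **LBP**: rotation-invariant uniform (riu2) local binary patterns at
  (radius, neighbors) = (1, 8), (3, 16), (5, 24) — parallel lists, standard
  multiscale practice — with one normalized (P+2)-bin histogram per scale,
  concatenated (length 54). Codes are taken from the patch interior (one
  radius margin) so no neighbor is sampled outside the patch.
* **GLCM**: patch intensities are quantized linearly over the patch's own
  min–max range into 16 levels; symmetric, normalized co-occurrence
  matrices at distance 1 in the four directions 0°/45°/90°/135° are
  summarized by a 13-statistic panel (mean, variance, correlation,
  contrast, dissimilarity, homogeneity, angular second moment, entropy,
  sum average/variance/entropy, difference variance/entropy — the Haralick
  core plus the Baraldi-style additions), averaged over directions. A
  single-level (degenerate) patch has correlation defined as 0.

Per image, the elementwise mean and population std of the per-patch
vectors over all kept patches are concatenated (means block, then stds). A
500-tree random forest provides the image posterior as its vote fraction.
Features are computed on raw (un-whitened) intensities: GLCM statistics
are deliberately contrast-dependent, and LBP only uses ordinal
comparisons. The SVM variant of the original comparison is not
implemented. Baselines skip rotation augmentation by default (riu2 is
rotation invariant; the GLCM panel is averaged over four directions).

`skimage.feature.local_binary_pattern` and `graycomatrix` provide the
underlying primitives; sum/difference statistics are computed from the
matrices directly. Both pipelines are cross-checked against naive
brute-force reimplementations in the test suite.

### Transfer-learning input chain

For whole-image classifiers expecting 8-bit RGB input, a frame is
dynamically compressed with the percentile rule
I₈ = 255/(P99.5 − P0.5)·(I − P0.5) (percentiles over in-field pixels only;
round half-up, clip to [0, 255]; a constant frame maps to zeros with a
warning), then the centered maximum square inside the disc is cropped
(side = floor(√2·r), floored so the square never exits the field — this
discards 1 − 2/π ≈ 36% of the field area), replicated to three channels
and anti-alias resized to 224×224 (≈0.55× for the canonical 407-px crop).
Fine-tuning a pretrained network is exposed only as this input contract;
no pretrained weights are shipped or downloaded.

### Evaluation protocol

Leave-one-patient-out (LOPO) cross-validation: one fold per patient, the
fold's test set being exactly that patient's frames. Augmentation and
balancing touch the training split only; a model is trained from scratch in
every fold. Per-frame probabilities from all folds are concatenated into a
single vector before ROC/AUC or threshold metrics are computed — per-patient
class mixes vary so much that fold-wise accuracies would mostly reflect
each patient's label distribution. The ROC is a threshold sweep over unique
scores (ties produce diagonal segments, the Mann–Whitney convention); AUC
is trapezoidal. Accuracy, sensitivity (carcinogenic positive) and
specificity are reported at threshold 0.5, canonical because the softmax
posterior is symmetric. A frame with zero valid patches has undefined p(I);
it is excluded from metrics and counted in `n_undefined`.

## Synthetic cohort

No public CLE dataset of this kind exists, so the package ships a generator
whose purpose is statistical control for end-to-end testing of geometry,
fusion, training and cross-validation — not photorealism. Defaults: 6
patients × 40 frames at 576×576, half carcinogenic; every patient carries a
lesion, and the normal frames cycle through the three physiological
recording sites (alveolar ridge, inner labium, hard palate) so LOPO folds
mix classes, as in the clinical design.

* **Normal texture**: Voronoi-like tessellation around blue-noise seed
  points (jittered grid, a cheap Poisson-disc approximation) at mean cell
  diameter 28 px; bright Gaussian-profile ridges (amplitude 26,000 over an
  11,000 interior, half-width 2.4 px) on cell boundaries.
* **Carcinogenic texture**: elevated background at 24,000 (leakage), low-
  coherence Gaussian-blob texture (no connected ridge network), and dark
  elliptical cell clusters (≈0.9 per 100×100 px, intensity 3,000–6,000).
* Additive Gaussian noise (σ 1,200), circular field mask (outside = 0),
  16-bit clipping. Texture parameters are jittered per patient (relative
  sd 0.1) to create between-patient variation.
* **Artifacts** at configurable per-frame rates (default 8% boxed noise,
  4% motion shear band, 4% dark occlusion) are recorded in the manifest as
  rectangle annotations, exactly as a clinician would annotate them; a
  whole-frame noise variant returns an exclusion flag instead, mirroring
  quality triage.

What the generator does *not* emulate: optical vignetting, fluorescein
pharmacokinetics, depth effects, video correlation within sequences beyond
shared patient parameters, dysplasia-grade intermediate classes, and the
heavy-tailed artifact spectrum of real recordings. Passing tests therefore
demonstrate that the pipeline's geometry, training and protocol work and
can separate texture classes of this kind — not clinical performance.

## Problem sizes and numerical choices

The test suite exercises LOPO runs at desk scale: per fold the training
split is stratified-subsampled (≤30 frames for the default cohort, patch
pool capped at 600) and the CNN trains 3–4 epochs at batch 128 — the
generator's textures are separable enough that this budget saturates
performance (patch-level held-out AUC reaches 1.0 within 4 epochs). The
published-scale schedule (60 epochs, batch 256, no caps) remains the
library default.

Other numerical conventions: percentages round half-up (reproduces the
published cohort table exactly); whitening declares a patch degenerate
below std 1e-8; Eq.-style closed intervals are used consistently for patch
rectangles, artifact boxes (0-based inclusive) and the area indicator;
downscaling maps pixel-center coordinates as (c + ½)f − ½ so a full-field
disc stays the inscribed disc; artifact boxes scale conservatively
(covering rectangle). Undefined image probabilities propagate as explicit
missing values rather than 0.5.

## Known limitations

* The CNN runs on CPU via BLAS; it is adequate for the cohort sizes here
  but not for clinical-scale training.
* Max-pooling breaks gradient ties by first argmax (deterministic); pool
  windows that do not tile the feature map exactly drop the trailing
  rows/columns (80-px inputs lose one row/column after the first pool).
* The published clinical accuracies cannot be reproduced without the
  original 12-patient dataset; the acceptance quantities are restricted to
  desk-verifiable geometry, architecture and bookkeeping values plus
  property-based checks on the synthetic cohort.
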