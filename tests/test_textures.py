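"""LBP / GLCM feature pipelines against naive reimplementations."""

import math

import numpy as np
import pytest

from clippf.evaluate import roc_auc
from clippf.patches import Patch
from clippf.textures import (
    GLCM_FEATURE_NAMES,
    GLCMConfig,
    ImageFeatureVector,
    LBPConfig,
    aggregate_image_features,
    glcm_features,
    image_feature_vector,
    lbp_patch_histogram,
    quantize_patch,
    rf_classify,
)


def _patch(pixels, label="normal"):
    a = np.asarray(pixels, np.float32)
    return Patch(
        pixels=a, corners=(0, a.shape[1] - 1, 0, a.shape[0] - 1),
        label=label, patient_id="p",
    )


# ---------------------------------------------------------------------------
# independent riu2 LBP oracle (bilinear sampling identical to the standard
# circular-neighbor definition)


def _bilinear(img, r, c):
    minr, minc = math.floor(r), math.floor(c)
    maxr, maxc = math.ceil(r), math.ceil(c)
    dr, dc = r - minr, c - minc

    def px(i, j):
        if 0 <= i < img.shape[0] and 0 <= j < img.shape[1]:
            return img[i, j]
        return 0.0

    top = (1 - dc) * px(minr, minc) + dc * px(minr, maxc)
    bottom = (1 - dc) * px(maxr, minc) + dc * px(maxr, maxc)
    return (1 - dr) * top + dr * bottom


def riu2_histogram_oracle(img, P, R):
    img = np.asarray(img, np.float64)
    rp = -R * np.sin(2 * np.pi * np.arange(P) / P)
    cp = R * np.cos(2 * np.pi * np.arange(P) / P)
    codes = []
    for r in range(R, img.shape[0] - R):
        for c in range(R, img.shape[1] - R):
            bits = [
                1 if _bilinear(img, r + rp[i], c + cp[i]) - img[r, c] >= 0 else 0
                for i in range(P)
            ]
            changes = sum(
                bits[i] != bits[(i + 1) % P] for i in range(P)
            )
            codes.append(sum(bits) if changes <= 2 else P + 1)
    hist = np.bincount(codes, minlength=P + 2).astype(float)
    return hist / hist.sum()


class TestLBP:
    def test_histogram_length_and_normalization(self):
        rng = np.random.default_rng(0)
        h = lbp_patch_histogram(_patch(rng.integers(0, 65535, (80, 80))))
        assert len(h) == 10 + 18 + 26 == 54
        assert h.sum() == pytest.approx(3.0)  # one unit mass per scale

    def test_constant_patch_masses_uniform_bin(self):
        h = lbp_patch_histogram(_patch(np.full((80, 80), 700)))
        # all-neighbors-equal -> code P (all bits set, zero transitions)
        for offset, P in ((0, 8), (10, 16), (28, 24)):
            assert h[offset + P] == pytest.approx(1.0)

    def test_rotation_invariance_quarter_turn(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 65535, (80, 80)).astype(np.float32)
        h1 = lbp_patch_histogram(_patch(img))
        h2 = lbp_patch_histogram(_patch(np.rot90(img)))
        np.testing.assert_allclose(h1, h2, atol=1e-12)

    @pytest.mark.parametrize("kind", ["step_edge", "random"])
    def test_matches_brute_force_oracle(self, kind):
        if kind == "step_edge":
            img = np.zeros((12, 12))
            img[:, 6:] = 1000.0
        else:
            img = np.random.default_rng(2).integers(0, 4096, (12, 12)).astype(float)
        config = LBPConfig(radii=(1,), neighbors=(8,))
        got = lbp_patch_histogram(_patch(img), config)
        expected = riu2_histogram_oracle(img, P=8, R=1)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            lbp_patch_histogram(_patch(np.zeros((8, 8))))

    def test_monotone_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 2048, (40, 40)).astype(float)
        h1 = lbp_patch_histogram(_patch(img))
        h2 = lbp_patch_histogram(_patch(img * 13.0))
        np.testing.assert_allclose(h1, h2, atol=1e-12)


# ---------------------------------------------------------------------------
# GLCM oracle: naive double-loop co-occurrence counting


def glcm_matrix_oracle(q, dr, dc, levels):
    counts = np.zeros((levels, levels))
    h, w = q.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[q[r, c], q[r2, c2]] += 1
    counts = counts + counts.T  # symmetric
    return counts / counts.sum()


class TestGLCM:
    def test_constant_patch_degenerate_features(self):
        f = dict(zip(GLCM_FEATURE_NAMES, glcm_features(_patch(np.full((80, 80), 42)))))
        assert f["contrast"] == 0.0
        assert f["homogeneity"] == pytest.approx(1.0)
        assert f["energy"] == pytest.approx(1.0)
        assert f["correlation"] == 0.0  # undefined variance -> 0 by convention

    def test_checkerboard_contrast_and_energy(self):
        q = np.indices((8, 8)).sum(axis=0) % 2
        patch = _patch(q * 1000.0)
        config = GLCMConfig(levels=2, angles=(0.0,))
        f = dict(zip(GLCM_FEATURE_NAMES, glcm_features(patch, config)))
        assert f["contrast"] == pytest.approx(1.0)
        assert f["energy"] == pytest.approx(0.5)
        assert f["dissimilarity"] == pytest.approx(1.0)

    def test_features_match_naive_cooccurrence_counter(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            img = rng.integers(0, 65535, (8, 8)).astype(np.float32)
            patch = _patch(img)
            config = GLCMConfig(levels=4)
            got = glcm_features(patch, config)
            q = quantize_patch(img, 4)
            offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]  # 0,45,90,135 deg
            mats = [glcm_matrix_oracle(q, dr, dc, 4) for dr, dc in offsets]
            expected = np.mean([_stats_oracle(m) for m in mats], axis=0)
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_quantization_spans_levels(self):
        rng = np.random.default_rng(6)
        q = quantize_patch(rng.uniform(0, 65535, (80, 80)), 16)
        assert q.min() == 0 and q.max() == 15


def _stats_oracle(P):
    """Feature panel recomputed with explicit loops over matrix cells."""
    L = P.shape[0]
    px = P.sum(axis=1)
    mu = sum(i * px[i] for i in range(L))
    var = sum((i - mu) ** 2 * px[i] for i in range(L))
    feats = dict.fromkeys(GLCM_FEATURE_NAMES, 0.0)
    feats["mean"] = mu
    feats["variance"] = var
    p_sum = np.zeros(2 * L - 1)
    p_diff = np.zeros(L)
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            p_sum[i + j] += p
            p_diff[abs(i - j)] += p
            feats["contrast"] += (i - j) ** 2 * p
            feats["dissimilarity"] += abs(i - j) * p
            feats["homogeneity"] += p / (1 + (i - j) ** 2)
            feats["energy"] += p * p
            if p > 0:
                feats["entropy"] -= p * np.log2(p)
            if var > 1e-12:
                feats["correlation"] += (i - mu) * (j - mu) * p / var
    sa = sum(k * p_sum[k] for k in range(2 * L - 1))
    feats["sum_average"] = sa
    feats["sum_variance"] = sum((k - sa) ** 2 * p_sum[k] for k in range(2 * L - 1))
    feats["sum_entropy"] = -sum(p * np.log2(p) for p in p_sum if p > 0)
    dm = sum(k * p_diff[k] for k in range(L))
    feats["difference_variance"] = sum((k - dm) ** 2 * p_diff[k] for k in range(L))
    feats["difference_entropy"] = -sum(p * np.log2(p) for p in p_diff if p > 0)
    return np.array([feats[name] for name in GLCM_FEATURE_NAMES])


class TestAggregation:
    def test_single_patch_stds_zero(self):
        out = aggregate_image_features([np.array([1.0, 3.0])])
        np.testing.assert_array_equal(out, [1.0, 3.0, 0.0, 0.0])

    def test_two_identical_patches_stds_zero(self):
        out = aggregate_image_features([np.array([2.0, 4.0])] * 2)
        np.testing.assert_array_equal(out, [2.0, 4.0, 0.0, 0.0])

    def test_hand_arithmetic(self):
        out = aggregate_image_features([np.array([1.0, 3.0]), np.array([3.0, 5.0])])
        np.testing.assert_array_equal(out, [2.0, 4.0, 1.0, 1.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no valid patches"):
            aggregate_image_features([])

    def test_patch_order_invariance(self):
        rng = np.random.default_rng(8)
        vecs = [rng.uniform(size=5) for _ in range(6)]
        a = aggregate_image_features(vecs)
        b = aggregate_image_features(vecs[::-1])
        np.testing.assert_allclose(a, b, atol=1e-14)


class TestRandomForest:
    def _vec(self, values, label):
        return ImageFeatureVector(
            values=np.asarray(values, float), label=label, patient_id="p"
        )

    def test_memorized_point_scores_high(self):
        rng = np.random.default_rng(9)
        train = [self._vec(rng.uniform(size=4), "normal") for _ in range(20)]
        target = rng.uniform(size=4)
        train += [self._vec(target, "carcinogenic") for _ in range(20)]
        probs = rf_classify(train, [self._vec(target, "carcinogenic")], 100, 0)
        assert probs[0] > 0.9

    def test_random_labels_give_chance_auc(self):
        rng = np.random.default_rng(10)
        mk = lambda lab: self._vec(rng.uniform(size=6), lab)
        train = [mk("normal") for _ in range(40)] + [
            mk("carcinogenic") for _ in range(40)
        ]
        test = [mk("normal") for _ in range(40)] + [
            mk("carcinogenic") for _ in range(40)
        ]
        probs = rf_classify(train, test, 200, 1)
        labels = [0] * 40 + [1] * 40
        _, auc = roc_auc(probs, labels)
        assert 0.3 <= auc <= 0.7

    def test_feature_length_mismatch_rejected(self):
        train = [self._vec([1, 2], "normal"), self._vec([2, 1], "carcinogenic")]
        with pytest.raises(ValueError, match="length"):
            rf_classify(train, [self._vec([1, 2, 3], "normal")])


def test_image_feature_vector_shape_and_metadata():
    rng = np.random.default_rng(11)
    patches = [
        _patch(rng.integers(0, 65535, (80, 80)), label="carcinogenic")
        for _ in range(3)
    ]
    v = image_feature_vector(patches, "lbp")
    assert v.values.shape == (108,)  # 54 means + 54 stds
    assert v.label == "carcinogenic"
    g = image_feature_vector(patches, "glcm")
    assert g.values.shape == (2 * len(GLCM_FEATURE_NAMES),)
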