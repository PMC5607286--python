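"""Patch grid geometry, field/artifact filtering, whitening, augmentation."""

import numpy as np
import pytest

from clippf import (
    ArtifactBox,
    augment_rotations,
    balance_classes,
    downscale_image,
    extract_patches,
    plan_patch_grid,
    whiten_patch,
)
from clippf.patches import Patch, rotate_frame

from conftest import make_frame


def full_field_frame(size=288, value=None, seed=0, **kw):
    rng = np.random.default_rng(seed)
    pixels = (
        np.full((size, size), value, np.uint16)
        if value is not None
        else rng.integers(0, 65536, (size, size), dtype=np.uint16)
    )
    return make_frame(pixels, **kw)


class TestDownscale:
    def test_half_size_scales_dims_and_geometry(self):
        frame = full_field_frame(576)
        small = downscale_image(frame, 0.5)
        assert small.pixels.shape == (288, 288)
        assert small.field_radius == 144.0
        assert small.field_center == (143.5, 143.5)

    def test_factor_one_is_identity(self):
        frame = full_field_frame(64)
        assert downscale_image(frame, 1.0) is frame

    def test_constant_image_is_mean_preserved(self):
        frame = full_field_frame(64, value=5000)
        small = downscale_image(frame, 0.5)
        assert np.all(small.pixels == 5000)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            downscale_image(full_field_frame(64), 0.0)


class TestPatchGrid:
    def test_288_grid_positions(self):
        grid = plan_patch_grid((288, 288), 80, 40)
        assert grid.xs == [24, 64, 104, 144, 184]
        assert grid.ys == grid.xs

    def test_576_grid_positions(self):
        grid = plan_patch_grid((576, 576), 80, 40)
        assert len(grid.xs) == 13
        assert grid.xs[0] == 8 and grid.xs[-1] == 488
        assert 248 in grid.xs  # a patch exactly centered

    def test_exact_fit_single_candidate(self):
        grid = plan_patch_grid((80, 80), 80, 40)
        assert grid.candidate_positions == [(0, 0)]

    def test_parity_mismatch_rejected(self):
        with pytest.raises(ValueError, match="even"):
            plan_patch_grid((287, 288), 80, 40)

    def test_grid_symmetric_about_center(self):
        grid = plan_patch_grid((288, 288), 80, 40)
        center = (288 - 80) / 2
        assert sorted(2 * center - np.array(grid.xs)) == grid.xs


class TestExtractPatches:
    def test_full_field_keeps_21_of_25(self):
        patches = extract_patches(full_field_frame(288))
        assert len(patches) == 21
        corners = {(p.corners[0], p.corners[2]) for p in patches}
        for corner in [(24, 24), (184, 24), (24, 184), (184, 184)]:
            assert corner not in corners

    def test_corner_quadruple_inclusive(self):
        patches = extract_patches(full_field_frame(288))
        for p in patches:
            c1, c2, c3, c4 = p.corners
            assert c2 - c1 + 1 == 80 and c4 - c3 + 1 == 80

    def test_central_artifact_removes_nine_patches(self):
        frame = full_field_frame(288)
        frame.artifact_boxes.append(ArtifactBox(104, 104, 183, 183))
        kept = extract_patches(frame)
        assert len(kept) == 12
        # brute-force rectangle intersection over the 21 field patches
        clean = extract_patches(full_field_frame(288))
        expected = [
            p
            for p in clean
            if p.corners[1] < 104 or p.corners[0] > 183
            or p.corners[3] < 104 or p.corners[2] > 183
        ]
        assert {p.corners for p in kept} == {p.corners for p in expected}

    def test_whole_frame_artifact_removes_all(self):
        frame = full_field_frame(288)
        frame.artifact_boxes.append(ArtifactBox(0, 0, 287, 287))
        assert extract_patches(frame) == []

    def test_field_inclusion_matches_per_pixel_brute_force(self):
        """Corner test agrees with checking all 6,400 pixel centers."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            size = int(rng.integers(180, 320))
            if (size - 80) % 2:
                size += 1
            cx = float(rng.uniform(size / 2 - 15, size / 2 + 15))
            cy = float(rng.uniform(size / 2 - 15, size / 2 + 15))
            radius = float(rng.uniform(60, size / 2))
            frame = make_frame(
                np.zeros((size, size), np.uint16),
                field_center=(cx, cy),
                field_radius=radius,
            )
            kept = {(p.corners[0], p.corners[2]) for p in extract_patches(frame)}
            grid = plan_patch_grid((size, size), 80, 40)
            brute = set()
            for x0 in grid.xs:
                for y0 in grid.ys:
                    xs, ys = np.meshgrid(
                        np.arange(x0, x0 + 80), np.arange(y0, y0 + 80)
                    )
                    if np.all((xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2):
                        brute.add((x0, y0))
            assert kept == brute


class TestWhitening:
    def _patch(self, pixels):
        return Patch(
            pixels=np.asarray(pixels, np.float32),
            corners=(0, 79, 0, 79),
            label="normal",
            patient_id="p",
        )

    def test_zero_mean_unit_std(self):
        rng = np.random.default_rng(0)
        w = whiten_patch(self._patch(rng.uniform(0, 65535, (80, 80))))
        assert abs(w.pixels.mean()) < 1e-6
        assert abs(w.pixels.std() - 1) < 1e-4

    def test_constant_patch_maps_to_zeros(self):
        w = whiten_patch(self._patch(np.full((80, 80), 500.0)))
        assert np.all(w.pixels == 0)

    def test_half_zero_half_two_gives_plus_minus_one(self):
        pixels = np.zeros((80, 80))
        pixels[:40] = 2.0
        w = whiten_patch(self._patch(pixels))
        assert set(np.unique(w.pixels)) == {-1.0, 1.0}

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.uniform(0, 1000, (80, 80))
            a, b = rng.uniform(0.1, 50), rng.uniform(-500, 500)
            w1 = whiten_patch(self._patch(x)).pixels
            w2 = whiten_patch(self._patch(a * x + b)).pixels
            np.testing.assert_allclose(w1, w2, atol=1e-4)


class TestAugmentation:
    def test_fold_two_triples_count_and_tags(self):
        frames = [full_field_frame(96, seed=i) for i in range(10)]
        out = augment_rotations(frames, fold_factor=2, rng_seed=0)
        assert len(out) == 30
        assert sum(f.augmented for f in out) == 20
        assert all(not f.augmented for f in out[:10])

    def test_fold_zero_originals_only(self):
        frames = [full_field_frame(96)]
        out = augment_rotations(frames, 0, 0)
        assert [id(f) for f in out] == [id(f) for f in frames]

    def test_zero_rotation_is_identity_inside_field(self):
        frame = full_field_frame(96, seed=5)
        copy = rotate_frame(frame, 0.0)
        np.testing.assert_array_equal(copy.pixels, frame.pixels)
        assert copy.augmented

    def test_rotation_preserves_label_and_patient(self):
        frame = full_field_frame(
            96, label="carcinogenic", location="lesion", patient="p7"
        )
        out = augment_rotations([frame], 2, rng_seed=1)
        assert all(f.label == "carcinogenic" and f.patient_id == "p7" for f in out)

    def test_test_split_rejected(self):
        with pytest.raises(ValueError, match="test"):
            augment_rotations([full_field_frame(96)], 2, 0, split="test")


class TestBalancing:
    def _cohort(self, n_normal, n_carc, n_aug_normal):
        frames = []
        for i in range(n_normal):
            f = full_field_frame(64, seed=i)
            f.augmented = i < n_aug_normal
            frames.append(f)
        for i in range(n_carc):
            frames.append(
                full_field_frame(
                    64, seed=100 + i, label="carcinogenic", location="lesion"
                )
            )
        return frames

    def test_majority_augmented_removed_until_equal(self):
        out = balance_classes(self._cohort(30, 24, 6), rng_seed=0)
        labels = [f.label for f in out]
        assert labels.count("normal") == labels.count("carcinogenic") == 24

    def test_already_balanced_unchanged(self):
        frames = self._cohort(5, 5, 2)
        out = balance_classes(frames, 0)
        assert [id(f) for f in out] == [id(f) for f in frames]

    def test_exhaustion_warns_and_keeps_originals(self):
        with pytest.warns(UserWarning, match="imbalance"):
            out = balance_classes(self._cohort(30, 24, 3), rng_seed=0)
        labels = [f.label for f in out]
        assert labels.count("normal") == 27
        assert sum(f.augmented for f in out) == 0

    def test_never_removes_originals(self):
        frames = self._cohort(30, 24, 10)
        out = balance_classes(frames, rng_seed=1)
        kept = {id(f) for f in out}
        assert all(id(f) in kept for f in frames if not f.augmented)
        labels = [f.label for f in out]
        assert labels.count("normal") == labels.count("carcinogenic") == 24
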