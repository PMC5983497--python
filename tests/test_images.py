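"""Uniform-region selection, QC and intensity extraction."""

import numpy as np
import pytest

from biliscreen import (
    ArtifactSpec,
    QcThresholds,
    RegionMask,
    SkinImage,
    block_summaries,
    extract_intensity,
    inject_artifacts,
    qc_image,
    select_uniform_region,
)
from biliscreen.images import ImageError, read_image, write_image


def brute_force_best_window(pixels, k):
    """Exhaustive window scan oracle: minimum summed channel variance,
    first (row, col) on ties."""
    h, w, _ = pixels.shape
    best, best_pos = None, None
    for r in range(h - k + 1):
        for c in range(w - k + 1):
            win = pixels[r : r + k, c : c + k].astype(np.float64)
            score = sum(win[:, :, ch].var() for ch in range(3))
            if best is None or score < best - 1e-9:
                best, best_pos = score, (r, c)
    return best_pos, best


class TestRegionSelection:
    def test_constant_image_ties_break_top_left(self, constant_image):
        mask = select_uniform_region(constant_image, 8)
        rows, cols = np.nonzero(mask.mask)
        assert rows.min() == 0 and cols.min() == 0
        assert mask.n_pixels == 64

    def test_noisy_quadrant_excluded(self, rng):
        px = np.full((16, 16, 3), 120, dtype=np.uint8)
        px[:8, :8] = rng.integers(0, 256, size=(8, 8, 3))
        mask = select_uniform_region(SkinImage(px), 8)
        assert not mask.mask[:8, :8].any()

    def test_matches_brute_force_scan(self, rng):
        for _ in range(20):
            px = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
            image = SkinImage(px)
            mask = select_uniform_region(image, 8)
            rows, cols = np.nonzero(mask.mask)
            (br, bc), best = brute_force_best_window(px, 8)
            win = px[rows.min() : rows.min() + 8, cols.min() : cols.min() + 8]
            score = sum(win[:, :, ch].astype(np.float64).var() for ch in range(3))
            assert score == pytest.approx(best, abs=1e-9)

    def test_selected_window_beats_every_candidate(self, rng):
        px = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        image = SkinImage(px)
        mask = select_uniform_region(image, 6)
        rows, cols = np.nonzero(mask.mask)
        r0, c0 = rows.min(), cols.min()
        sel = px[r0 : r0 + 6, c0 : c0 + 6].astype(np.float64)
        sel_score = sum(sel[:, :, ch].var() for ch in range(3))
        for r in range(11):
            for c in range(11):
                win = px[r : r + 6, c : c + 6].astype(np.float64)
                assert sel_score <= sum(win[:, :, ch].var() for ch in range(3)) + 1e-9

    def test_invariant_under_constant_shift(self, rng):
        px = rng.integers(0, 180, size=(20, 20, 3), dtype=np.uint8)
        m1 = select_uniform_region(SkinImage(px), 8)
        m2 = select_uniform_region(SkinImage(px + 50), 8)
        assert np.array_equal(m1.mask, m2.mask)

    def test_window_larger_than_image_rejected(self, constant_image):
        with pytest.raises(ImageError):
            select_uniform_region(constant_image, 32)


class TestQc:
    def full_mask(self, image):
        return RegionMask(np.ones(image.pixels.shape[:2], dtype=bool))

    def test_clean_constant_image_passes(self, constant_image):
        report = qc_image(constant_image, self.full_mask(constant_image))
        assert report.passed and report.reasons == []

    def test_saturation_excess_fails(self, rng):
        px = np.full((20, 20, 3), 150, dtype=np.uint8)
        idx = rng.choice(400, size=80, replace=False)  # 20% saturated
        px.reshape(400, 3)[idx, 0] = 255
        report = qc_image(SkinImage(px), RegionMask(np.ones((20, 20), dtype=bool)))
        assert not report.passed
        assert "saturation_excess" in report.reasons
        assert report.saturated_fraction == pytest.approx(0.2)

    def test_hair_artifacts_fail_qc(self):
        """The 3-SD local rule flags one-sided hair contamination only while
        it stays under ~10% of the region (Chebyshev bound 1/9), so the
        excess test uses a stricter configured threshold."""
        px = np.full((32, 32, 3), 150, dtype=np.uint8)
        spec = ArtifactSpec(hair_streak_count=4, hair_streak_darkening=90, artifact_seed=3)
        image = inject_artifacts(SkinImage(px), spec)
        frac = image.metadata["artifact_pixels"] / 1024
        assert 0.04 < frac < 0.10
        report = qc_image(
            image,
            RegionMask(np.ones((32, 32), dtype=bool)),
            QcThresholds(max_artifact_fraction=0.04),
        )
        assert not report.passed
        assert "artifact_excess" in report.reasons
        # generator metadata and the QC measurement agree on the fraction
        assert report.artifact_fraction == pytest.approx(frac)

    def test_small_region_fails(self, constant_image):
        mask = np.zeros((16, 16), dtype=bool)
        mask[:3, :3] = True
        report = qc_image(constant_image, RegionMask(mask), QcThresholds(min_region_pixels=16))
        assert report.reasons == ["region_too_small"]


class TestExtraction:
    def test_constant_image_means(self, constant_image):
        mask = RegionMask(np.ones((16, 16), dtype=bool))
        s = extract_intensity(constant_image, mask)
        assert np.array_equal(s.mean, [200.0, 180.0, 160.0])
        assert np.array_equal(s.median, [200.0, 180.0, 160.0])
        assert s.n_pixels == 256 and s.aggregation_block == 1

    def test_hand_computed_2x2_green(self):
        px = np.zeros((8, 8, 3), dtype=np.uint8)
        px[0, 0, 1], px[0, 1, 1], px[1, 0, 1], px[1, 1, 1] = 100, 110, 120, 130
        mask = np.zeros((8, 8), dtype=bool)
        mask[:2, :2] = True
        s = extract_intensity(SkinImage(px), RegionMask(mask))
        assert s.mean[1] == 115.0
        assert s.median[1] == 115.0
        assert s.p25[1] == 107.5 and s.p75[1] == 122.5  # linear interpolation

    def test_matches_naive_loop_oracle(self, rng):
        """Arithmetic-mean extraction equals a per-pixel double loop."""
        for _ in range(100):
            px = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
            mask = rng.uniform(size=(16, 16)) < 0.6
            if not mask.any():
                mask[0, 0] = True
            s = extract_intensity(SkinImage(px), RegionMask(mask))
            for ch in range(3):
                total, count = 0.0, 0
                for r in range(16):
                    for c in range(16):
                        if mask[r, c]:
                            total += float(px[r, c, ch])
                            count += 1
                assert s.mean[ch] == pytest.approx(total / count, abs=1e-12)

    def test_quartile_ordering_and_range(self, rng):
        for _ in range(25):
            px = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
            s = extract_intensity(SkinImage(px), RegionMask(np.ones((16, 16), dtype=bool)))
            assert np.all(s.p25 <= s.median) and np.all(s.median <= s.p75)
            assert np.all(s.mean >= 0) and np.all(s.mean <= 255)

    def test_empty_mask_rejected(self, constant_image):
        with pytest.raises(ImageError):
            extract_intensity(constant_image, RegionMask(np.zeros((16, 16), dtype=bool)))


class TestBlockSummaries:
    def test_constant_image_blocks_equal_pixels(self, constant_image):
        mask = RegionMask(np.ones((16, 16), dtype=bool))
        raw = extract_intensity(constant_image, mask)
        for b in (2, 3, 4):
            blk = block_summaries(constant_image, mask, b)
            assert np.array_equal(blk.mean, raw.mean)
            assert np.array_equal(blk.median, raw.median)
            assert blk.aggregation_block == b

    def test_hand_computed_4x4_example(self):
        """One 2x2 block of 100s and three of 200s: block values
        {100, 200, 200, 200}, mean 175, median 200."""
        px = np.full((8, 8, 3), 200, dtype=np.uint8)
        px[:2, :2] = 100
        mask = np.zeros((8, 8), dtype=bool)
        mask[:4, :4] = True
        s = block_summaries(SkinImage(px), RegionMask(mask), 2)
        assert np.all(s.mean == 175.0)
        assert np.all(s.median == 200.0)
        assert s.n_pixels == 16

    def test_block_mean_of_means_equals_overall_mean(self, rng):
        px = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        mask = RegionMask(np.ones((16, 16), dtype=bool))
        raw = extract_intensity(SkinImage(px), mask)
        blk = block_summaries(SkinImage(px), mask, 2)
        assert np.allclose(blk.mean, raw.mean, atol=1e-12)

    def test_too_few_blocks_rejected(self, constant_image):
        mask = np.zeros((16, 16), dtype=bool)
        mask[:4, :4] = True
        with pytest.raises(ImageError):
            block_summaries(constant_image, RegionMask(mask), 4)


def test_png_round_trip_preserves_pixels(tmp_path, rng):
    px = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
    image = SkinImage(px, subject_id="S001")
    path = tmp_path / "S001.png"
    write_image(image, path)
    back = read_image(path)
    assert np.array_equal(back.pixels, px)
    assert back.subject_id == "S001"
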