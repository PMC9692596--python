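import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.filters import threshold_otsu as skimage_otsu

from spioquant import (
    GrayImage,
    IntensityHistogram,
    ValidationError,
    binarize,
    first_minimum_threshold,
    histogram,
    otsu_threshold,
    overlay,
)

from conftest import brute_force_otsu


def _hist_from_counts(**level_counts):
    counts = np.zeros(256, dtype=np.int64)
    for level, n in level_counts.items():
        counts[int(level.lstrip("g"))] = n
    return IntensityHistogram(counts=counts)


class TestOtsu:
    def test_perfect_bimodal_separates_with_zero_variance(self):
        h = _hist_from_counts(g50=50, g200=50)
        res = otsu_threshold(h)
        assert 50 < res.threshold <= 200
        assert res.objective_curve.min() == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_single_level_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            otsu_threshold(_hist_from_counts(g128=100))

    def test_matches_brute_force_pixel_scan(self, rng):
        """Histogram-based search equals per-pixel exhaustive minimization."""
        for _ in range(30):
            if rng.uniform() < 0.5:
                px = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
            else:  # bimodal mixture, the realistic micrograph shape
                lo = rng.normal(rng.uniform(40, 90), 12, size=(64, 64))
                hi = rng.normal(rng.uniform(150, 210), 15, size=(64, 64))
                pick = rng.uniform(size=(64, 64)) < rng.uniform(0.1, 0.6)
                px = np.clip(np.where(pick, lo, hi), 0, 255).astype(np.uint8)
            img = GrayImage(pixels=px, pixel_size_nm=1.0)
            assert otsu_threshold(histogram(img)).threshold == brute_force_otsu(px)

    def test_partition_agrees_with_skimage(self, random_image):
        """Cross-check class membership against scikit-image's Otsu.

        Conventions differ (skimage classes are g <= t vs g > t), so the
        induced partitions are compared, not the raw threshold values.
        """
        t_ours = otsu_threshold(histogram(random_image)).threshold
        t_sk = skimage_otsu(random_image.pixels)
        ours_fg = random_image.pixels < t_ours
        sk_fg = random_image.pixels <= t_sk
        assert (ours_fg == sk_fg).all()

    def test_between_class_variance_identity(self, rng):
        """Minimizing intra-class variance == maximizing between-class variance."""
        counts = rng.integers(0, 50, size=256)
        counts[rng.integers(0, 256)] += 500  # ensure occupied
        h = IntensityHistogram(counts=counts)
        res = otsu_threshold(h)
        levels = np.arange(256, dtype=float)
        n = counts.sum()
        mu = (counts * levels).sum() / n
        best_t, best_between = None, -1.0
        for t in range(1, 256):
            n0 = counts[:t].sum()
            n1 = n - n0
            if n0 == 0 or n1 == 0:
                continue
            mu0 = (counts[:t] * levels[:t]).sum() / n0
            mu1 = (counts[t:] * levels[t:]).sum() / n1
            between = (n0 / n) * (mu0 - mu) ** 2 + (n1 / n) * (mu1 - mu) ** 2
            if between > best_between + 1e-9:
                best_between, best_t = between, t
        assert res.threshold == best_t

    def test_shift_robustness(self, rng):
        px = np.clip(rng.normal(120, 25, size=(48, 48)), 40, 200).astype(np.uint8)
        t0 = otsu_threshold(histogram(GrayImage(px, 1.0))).threshold
        for c in (-15, 10, 30):
            shifted = (px.astype(int) + c).astype(np.uint8)  # stays in [0,255]
            tc = otsu_threshold(histogram(GrayImage(shifted, 1.0))).threshold
            assert tc == t0 + c


class TestFirstMinimum:
    def test_unique_valley_is_selected(self):
        counts = np.zeros(256, dtype=np.int64)
        g = np.arange(256)
        counts[100:141] = 100 + (g[100:141] - 120) ** 2  # valley at 120
        res = first_minimum_threshold(IntensityHistogram(counts), smooth_window=1)
        assert res.threshold == 120
        assert res.method == "first_minimum"
        assert not res.fallback

    def test_monotone_histogram_falls_back_to_otsu(self):
        counts = np.zeros(256, dtype=np.int64)
        counts[50:200] = np.arange(150) + 1  # strictly increasing
        h = IntensityHistogram(counts)
        res = first_minimum_threshold(h, smooth_window=1)
        assert res.fallback
        assert res.threshold == otsu_threshold(h).threshold

    def test_bimodal_valley_lands_between_modes(self, rng):
        g = np.arange(256)
        counts = (
            3000 * np.exp(-((g - 60) ** 2) / (2 * 15**2))
            + 6000 * np.exp(-((g - 180) ** 2) / (2 * 20**2))
        ).astype(np.int64)
        res = first_minimum_threshold(IntensityHistogram(counts), smooth_window=5)
        assert 60 <= res.threshold <= 180
        # direct scan of the smoothed array reproduces the choice
        s = res.smoothed_counts
        first = int(np.flatnonzero(counts)[0])
        expected = next(
            gg for gg in range(max(first, 1), 255)
            if s[gg] < s[gg - 1] and s[gg] <= s[gg + 1]
        )
        assert res.threshold == expected

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            first_minimum_threshold(_hist_from_counts(g10=5, g200=5), smooth_window=4)


class TestBinarize:
    def test_boundary_pixel_goes_to_background(self):
        from spioquant.thresholding import ThresholdResult

        img = GrayImage(np.array([[10, 128, 200]], dtype=np.uint8), 1.0)
        seg = binarize(img, ThresholdResult(threshold=128, method="otsu"))
        assert seg.labels.tolist() == [[0, 255, 255]]

    def test_zero_threshold_empty_foreground(self, random_image):
        from spioquant.thresholding import ThresholdResult

        seg = binarize(random_image, ThresholdResult(threshold=0, method="otsu"))
        assert seg.foreground_count == 0

    @settings(deadline=None, max_examples=30)
    @given(t1=st.integers(0, 255), t2=st.integers(0, 255), seed=st.integers(0, 10))
    def test_partition_and_monotonicity(self, t1, t2, seed):
        from spioquant.thresholding import ThresholdResult

        rng = np.random.default_rng(seed)
        img = GrayImage(rng.integers(0, 256, size=(16, 16), dtype=np.uint8), 1.0)
        seg1 = binarize(img, ThresholdResult(threshold=t1, method="otsu"))
        seg2 = binarize(img, ThresholdResult(threshold=t2, method="otsu"))
        assert seg1.foreground_count + (seg1.labels == 255).sum() == img.pixels.size
        if t1 <= t2:
            assert seg1.foreground_count <= seg2.foreground_count


class TestOverlay:
    def test_background_keeps_grayscale_foreground_pure_red(self, random_image):
        from spioquant.thresholding import ThresholdResult

        seg = binarize(random_image, ThresholdResult(threshold=120, method="otsu"))
        rgb = overlay(random_image, seg)
        fg = seg.foreground_mask
        assert (rgb[fg] == (255, 0, 0)).all()
        assert (rgb[~fg] == random_image.pixels[~fg, np.newaxis]).all()
        assert ((rgb[:, :, 0] == 255) & (rgb[:, :, 1] == 0)).sum() >= fg.sum()

    def test_shape_mismatch_rejected(self, random_image):
        from spioquant.thresholding import ThresholdResult, SegmentedImage

        seg = SegmentedImage(
            labels=np.full((3, 3), 255, dtype=np.uint8),
            threshold_used=ThresholdResult(threshold=1, method="otsu"),
            pixel_size_nm=1.0,
        )
        with pytest.raises(ValidationError):
            overlay(random_image, seg)
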