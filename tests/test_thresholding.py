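"""Otsu binary/multilevel thresholding against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.filters import threshold_multiotsu, threshold_otsu

from bgikit.raster_core import ChannelHistogram, RasterImage
from bgikit.thresholding import (
    DegenerateHistogramError,
    QuantizedImage,
    ThresholdSet,
    areal_coverage,
    manual_threshold,
    multilevel_otsu,
    otsu_binary_threshold,
    quantize,
    within_class_variance,
)
from conftest import random_histogram


def brute_force_otsu(hist, n):
    """Lexicographic exhaustive search minimising within-class variance."""
    best, best_v = None, np.inf
    hi = int(np.flatnonzero(hist.counts).max())
    for combo in itertools.combinations(range(min(hi, 254) + 1), n):
        v = within_class_variance(hist, ThresholdSet(combo))
        if v < best_v - 1e-9:
            best_v, best = v, combo
    return best


class TestBinaryOtsu:
    def test_two_spike_tiebreak(self):
        counts = np.zeros(256, int)
        counts[0] = counts[255] = 50
        ts = otsu_binary_threshold(ChannelHistogram(counts))
        # any t separates the spikes; tie-break picks the smallest
        assert ts.levels == (0,)

    def test_outlier_assignment_matches_exhaustive(self):
        counts = np.zeros(256, int)
        counts[2] = counts[200] = 10
        counts[100] = 1
        hist = ChannelHistogram(counts)
        ts = otsu_binary_threshold(hist)
        assert ts.levels == brute_force_otsu(hist, 1)

    def test_degenerate_single_intensity(self):
        counts = np.zeros(256, int)
        counts[42] = 100
        with pytest.raises(DegenerateHistogramError):
            otsu_binary_threshold(ChannelHistogram(counts))

    def test_partition_matches_skimage(self, rng):
        for _ in range(20):
            px = rng.integers(0, 256, (30, 30)).astype(np.uint8)
            img = RasterImage(px)
            hist = ChannelHistogram(np.bincount(px.ravel(), minlength=256))
            t = otsu_binary_threshold(hist).levels[0]
            # skimage convention: foreground is px > t, i.e. t itself is
            # in the lower class, same as here
            assert (px <= t).sum() == (px <= threshold_otsu(px)).sum()


class TestMultilevelOtsu:
    def test_ten_thresholds_eleven_classes(self, rng):
        px = rng.integers(0, 256, (60, 60)).astype(np.uint8)
        hist = ChannelHistogram(np.bincount(px.ravel(), minlength=256))
        ts = multilevel_otsu(hist, 10)
        assert ts.n_thresholds == 10 and ts.n_classes == 11

    def test_eleven_spikes_each_own_class(self):
        counts = np.zeros(256, int)
        levels = np.arange(0, 256, 25)[:11]
        counts[levels] = 10
        ts = multilevel_otsu(ChannelHistogram(counts), 10)
        classes = ts.classify(levels)
        assert sorted(classes) == list(range(11))
        assert within_class_variance(ChannelHistogram(counts), ts) == 0.0

    def test_consistency_with_binary(self, rng):
        for _ in range(200):
            hist = random_histogram(rng, n_levels=int(rng.integers(3, 20)))
            assert multilevel_otsu(hist, 1).levels == otsu_binary_threshold(hist).levels

    @pytest.mark.parametrize("n", [2, 3])
    def test_matches_exhaustive_search_16_levels(self, rng, n):
        # reduced histograms (intensities 0..15) so enumeration is exact
        for _ in range(60):
            hist = random_histogram(rng, n_levels=int(rng.integers(n + 2, 16)),
                                    max_level=15)
            got = multilevel_otsu(hist, n).levels
            assert got == brute_force_otsu(hist, n)

    def test_threshold_values_match_skimage(self, rng):
        for _ in range(10):
            px = rng.integers(0, 256, (50, 50)).astype(np.uint8)
            hist = ChannelHistogram(np.bincount(px.ravel(), minlength=256))
            for nc in (3, 4, 5):
                ts = multilevel_otsu(hist, nc - 1)
                sk = threshold_multiotsu(px, classes=nc, nbins=256)
                assert list(ts.levels) == list(sk)

    def test_shift_equivariance(self, rng):
        for _ in range(20):
            hist = random_histogram(rng, n_levels=12, max_level=180)
            c = int(rng.integers(1, 60))
            shifted = ChannelHistogram(np.roll(hist.counts, c))
            for n in (1, 3):
                base = multilevel_otsu(hist, n).levels
                moved = multilevel_otsu(shifted, n).levels
                assert tuple(t + c for t in base) == moved

    def test_degenerate_too_few_levels(self):
        counts = np.zeros(256, int)
        counts[[10, 200]] = 50
        with pytest.raises(DegenerateHistogramError):
            multilevel_otsu(ChannelHistogram(counts), 10)


class TestQuantize:
    def test_single_threshold_classes(self):
        img = RasterImage(np.array([[0, 200]], np.uint8))
        q = quantize(img, ThresholdSet((127,)))
        assert q.class_map.tolist() == [[0, 1]]

    def test_threshold_value_goes_to_lower_class(self):
        img = RasterImage(np.array([[127, 128]], np.uint8))
        q = quantize(img, ThresholdSet((127,)))
        assert q.class_map.tolist() == [[0, 1]]

    def test_stretch_map_endpoints_and_midpoint(self):
        q = QuantizedImage(np.zeros((1, 1), int), n_classes=11)
        sm = q.stretch_map
        assert sm[0] == 0 and sm[10] == 255 and sm[5] == 128
        assert all(b > a for a, b in zip(sm, sm[1:]))

    def test_class_counts_partition(self, rng):
        px = rng.integers(0, 256, (30, 30)).astype(np.uint8)
        hist = ChannelHistogram(np.bincount(px.ravel(), minlength=256))
        q = quantize(RasterImage(px), multilevel_otsu(hist, 10))
        assert q.class_counts().sum() == px.size


class TestManualAndCoverage:
    def test_full_range_full_coverage(self, random_gray_image):
        mask = manual_threshold(random_gray_image, 0, 255)
        assert areal_coverage(mask) == 100.0

    def test_empty_range_hits_nothing(self):
        img = RasterImage(np.full((4, 4), 10, np.uint8))
        assert areal_coverage(manual_threshold(img, 0, 0)) == 0.0

    def test_coverage_counting(self, rng):
        px = rng.integers(0, 256, (30, 40)).astype(np.uint8)
        img = RasterImage(px)
        mask = manual_threshold(img, 0, 100)
        expected = 100.0 * (px <= 100).sum() / px.size
        assert areal_coverage(mask) == pytest.approx(expected)
        # coverage of the mask equals histogram counts in [low, high]
        counts = np.bincount(px.ravel(), minlength=256)
        assert mask.sum() == counts[:101].sum()

    def test_three_of_twelve(self):
        px = np.full((3, 4), 200, np.uint8)
        px[0, :3] = 10
        assert areal_coverage(manual_threshold(RasterImage(px), 0, 50)) == 25.0

    def test_invalid_range(self, random_gray_image):
        with pytest.raises(ValueError):
            manual_threshold(random_gray_image, 100, 50)

    def test_monotone_in_foreground_growth(self, rng):
        px = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        img = RasterImage(px)
        covs = [areal_coverage(manual_threshold(img, 0, hi)) for hi in (50, 120, 255)]
        assert covs == sorted(covs)
        assert all(0.0 <= c <= 100.0 for c in covs)

    def test_binary_quantized_dark_foreground(self):
        img = RasterImage(np.array([[0, 0], [0, 250]], np.uint8))
        q = quantize(img, ThresholdSet((100,)))
        assert areal_coverage(q) == 75.0
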