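import numpy as np
import pytest

from bgikit.raster_core import RasterImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_gray_image(rng):
    return RasterImage(rng.integers(0, 256, (50, 50), dtype=np.uint8).astype(np.uint8))


@pytest.fixture
def random_color_image(rng):
    return RasterImage(rng.integers(0, 256, (40, 40, 3)).astype(np.uint8))


def random_histogram(rng, n_levels=16, max_level=255, min_count=1, max_count=60):
    """Random sparse 256-bin histogram with `n_levels` distinct intensities."""
    from bgikit.raster_core import ChannelHistogram

    levels = rng.choice(max_level + 1, size=n_levels, replace=False)
    counts = np.zeros(256, dtype=np.int64)
    counts[levels] = rng.integers(min_count, max_count, n_levels)
    return ChannelHistogram(counts)
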