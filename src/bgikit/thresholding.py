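"""Binary and multilevel Otsu-style thresholding and areal coverage.

Otsu's criterion selects intensity thresholds that minimise the
count-weighted sum of within-class intensity variances — equivalently,
maximise the between-class variance.  The binary form splits a histogram
into foreground and background; the multilevel form generalises to N
thresholds and N+1 classes and is the first stage of the BGI score.

The multilevel optimum is found by exact dynamic programming over the
256-bin histogram using cumulative count / count*intensity / count*intensity^2
sums, so the global optimum is guaranteed even for N = 10 at negligible
cost; no stochastic search is involved and results are fully reproducible.

Threshold convention, applied everywhere in this package: a pixel with
intensity ``v <= t`` belongs to the class below threshold ``t`` (inclusive
upper bound on the lower class).  Class 0 always holds the darkest
intensities.  Ties between equally optimal threshold vectors are broken
toward the lexicographically smallest vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_core import ChannelHistogram, RasterImage

__all__ = [
    "ThresholdSet",
    "QuantizedImage",
    "DegenerateHistogramError",
    "otsu_binary_threshold",
    "multilevel_otsu",
    "within_class_variance",
    "quantize",
    "manual_threshold",
    "areal_coverage",
]


class DegenerateHistogramError(ValueError):
    """Histogram has too few distinct intensities to place the thresholds."""


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered threshold levels partitioning [0, 255] into ``n_classes``.

    ``levels`` are strictly increasing integers in [0, 254]; a pixel of
    intensity ``v`` belongs to class ``g`` = number of levels strictly
    below ``v`` (so ``v == level`` falls in the lower class).
    """

    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        lv = tuple(int(x) for x in self.levels)
        if len(lv) < 1:
            raise ValueError("at least one threshold level required")
        if any(not (0 <= t <= 254) for t in lv):
            raise ValueError(f"threshold levels must lie in [0, 254]: {lv}")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError(f"threshold levels must be strictly increasing: {lv}")
        object.__setattr__(self, "levels", lv)

    @property
    def n_thresholds(self) -> int:
        return len(self.levels)

    @property
    def n_classes(self) -> int:
        return len(self.levels) + 1

    def classify(self, values: np.ndarray) -> np.ndarray:
        """Class index for each intensity value (0 = darkest class)."""
        # searchsorted 'left' counts levels strictly below v, so v == level
        # lands in the lower class, matching the package-wide convention.
        return np.searchsorted(np.asarray(self.levels), np.asarray(values), side="left")


@dataclass(frozen=True)
class QuantizedImage:
    """Class-index map plus the display intensities for each class.

    ``stretch_map`` spreads the class indices over the full 0–255 range
    (class g -> round(g*255/N)), the contrast stretch used for the
    inspection images.
    """

    class_map: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        cm = np.asarray(self.class_map)
        if cm.ndim != 2:
            raise ValueError("class_map must be 2-D")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if cm.size and int(cm.max()) >= self.n_classes:
            raise ValueError("class index out of range")
        object.__setattr__(self, "class_map", cm.astype(np.int64))

    @property
    def stretch_map(self) -> tuple[int, ...]:
        n = self.n_classes - 1
        return tuple(int(np.floor(g * 255.0 / n + 0.5)) for g in range(self.n_classes))

    def class_counts(self) -> np.ndarray:
        """Pixel count per class, darkest class first."""
        return np.bincount(self.class_map.ravel(), minlength=self.n_classes)

    def stretched(self) -> RasterImage:
        """Display image with classes stretched across [0, 255]."""
        lut = np.asarray(self.stretch_map, dtype=np.uint8)
        return RasterImage(lut[self.class_map])


def _segment_cost_matrix(counts: np.ndarray) -> np.ndarray:
    """cost[i, j] = count-weighted within-class variance of bins i..j.

    For a segment with pixel count W, intensity sum S1 and squared sum S2
    the weighted variance is S2 - S1^2/W (0 for empty segments); +inf for
    j < i.
    """
    c = counts.astype(np.float64)
    v = np.arange(256, dtype=np.float64)
    cw = np.concatenate([[0.0], np.cumsum(c)])
    cs1 = np.concatenate([[0.0], np.cumsum(c * v)])
    cs2 = np.concatenate([[0.0], np.cumsum(c * v * v)])
    i = np.arange(256)[:, None]
    j = np.arange(256)[None, :]
    W = cw[j + 1] - cw[i]
    S1 = cs1[j + 1] - cs1[i]
    S2 = cs2[j + 1] - cs2[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = S2 - np.where(W > 0, S1 * S1 / np.where(W > 0, W, 1.0), 0.0)
    cost = np.where(W > 0, cost, 0.0)
    cost = np.where(j >= i, cost, np.inf)
    return cost


def within_class_variance(hist: ChannelHistogram, thresholds: ThresholdSet) -> float:
    """Total count-weighted within-class variance under a threshold set."""
    counts = hist.counts.astype(np.float64)
    v = np.arange(256, dtype=np.float64)
    bounds = [0, *[t + 1 for t in thresholds.levels], 256]
    total = 0.0
    for lo, hi in zip(bounds, bounds[1:]):
        w = counts[lo:hi].sum()
        if w > 0:
            s1 = (counts[lo:hi] * v[lo:hi]).sum()
            s2 = (counts[lo:hi] * v[lo:hi] ** 2).sum()
            total += s2 - s1 * s1 / w
    return float(total)


def multilevel_otsu(hist: ChannelHistogram, n_thresholds: int = 10) -> ThresholdSet:
    """Globally optimal multilevel Otsu thresholds by dynamic programming.

    Returns the strictly increasing vector of ``n_thresholds`` levels that
    minimises the total count-weighted within-class variance over the
    ``n_thresholds + 1`` classes.  For ``n_thresholds = 1`` this is exactly
    the classic binary Otsu threshold.

    Raises
    ------
    DegenerateHistogramError
        If the histogram does not have more nonempty bins than thresholds
        (no variance-reducing placement exists for all thresholds).
    """
    if n_thresholds < 1:
        raise ValueError("n_thresholds must be >= 1")
    if hist.n_nonempty_bins <= n_thresholds:
        raise DegenerateHistogramError(
            f"histogram has {hist.n_nonempty_bins} nonempty bins; "
            f"need more than {n_thresholds} to place {n_thresholds} thresholds"
        )

    cost = _segment_cost_matrix(hist.counts)
    n_classes = n_thresholds + 1

    # D[j] = optimal cost of splitting bins 0..j into (k+1) classes,
    # each covering >= 1 bin.  P[k][j] = first bin of the last class
    # (smallest arg min => lexicographically smallest thresholds on ties).
    D = cost[0, :].copy()  # k = 0: single class over bins 0..j
    preds = []
    for k in range(1, n_classes):
        # M[i, j] = D_prev[i-1] + cost[i, j] for the last class starting at i
        M = D[:-1, None] + cost[1:, :]
        P = np.argmin(M, axis=0) + 1
        D = np.take_along_axis(M, (P - 1)[None, :], axis=0)[0]
        # a split into k+1 nonempty bin ranges needs j >= k
        D[:k] = np.inf
        preds.append(P)

    levels = []
    j = 255
    for k in range(n_classes - 1, 0, -1):
        i = int(preds[k - 1][j])
        levels.append(i - 1)
        j = i - 1
    return ThresholdSet(tuple(sorted(levels)))


def otsu_binary_threshold(hist: ChannelHistogram) -> ThresholdSet:
    """Classic binary Otsu threshold (single level, two classes)."""
    return multilevel_otsu(hist, n_thresholds=1)


def quantize(img: RasterImage, thresholds: ThresholdSet) -> QuantizedImage:
    """Assign each pixel its threshold class (0 = darkest)."""
    if img.channels != 1:
        raise ValueError("quantize requires a 1-channel image")
    class_map = thresholds.classify(img.pixels)
    return QuantizedImage(class_map, n_classes=thresholds.n_classes)


def manual_threshold(img: RasterImage, low: int, high: int) -> np.ndarray:
    """Binary mask of pixels with intensity in the closed range [low, high].

    This is the manually-selected-range comparator: pixels inside the
    range are foreground (biofilm), all others background.
    """
    if img.channels != 1:
        raise ValueError("manual_threshold requires a 1-channel image")
    if not (0 <= low <= high <= 255):
        raise ValueError(f"require 0 <= low <= high <= 255, got [{low}, {high}]")
    px = img.pixels
    return (px >= low) & (px <= high)


def areal_coverage(mask_or_quantized, foreground_class: int = 0) -> float:
    """Percentage of pixels classified as foreground (biofilm).

    Accepts a boolean mask (``True`` = foreground) or a binary
    :class:`QuantizedImage`, whose foreground is the dark class
    (``foreground_class = 0``, the "black pixels" of the binary output).
    """
    if isinstance(mask_or_quantized, QuantizedImage):
        q = mask_or_quantized
        if q.n_classes != 2:
            raise ValueError("areal_coverage of a QuantizedImage requires N = 1")
        mask = q.class_map == foreground_class
    else:
        mask = np.asarray(mask_or_quantized, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty image has no areal coverage")
    return 100.0 * float(mask.sum()) / float(mask.size)
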