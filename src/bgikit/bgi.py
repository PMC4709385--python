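"""Biofilm Growth Intensity: ramp-filtered multilevel-threshold scoring.

A stained coupon photographed under diffuse light is darkest where the
biofilm is thickest, so darkness carries the signal.  The BGI score
captures it in three steps:

1. a multilevel Otsu threshold (N = 10 by default) partitions the
   channel histogram into N+1 intensity classes and stretches them over
   the display range;
2. a linear ramp filter reweights the per-class pixel counts — weight 0
   for the brightest class rising in equal steps of 1/N to weight 1 for
   the darkest class — producing the filtered histogram area A2;
3. BGI = 100 * A2 / A1, where A1 is the total pixel count of the
   analysed region.

BGI is 100 exactly when every pixel sits in the darkest class and 0 when
every pixel sits in the brightest; unlike areal coverage it responds to
density and thickness of growth, not just extent.  The score depends only
on the histogram, never on the spatial arrangement of pixels.

Channels are scored independently: the algorithm is applied to the
grayscale image and to each of the red, green and blue channels, each
with its own thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_core import (
    BLUE,
    GRAY,
    GREEN,
    RED,
    RasterImage,
    RegionOfInterest,
    compute_histogram,
    extract_roi,
    split_channels,
    to_grayscale,
)
from .thresholding import (
    DegenerateHistogramError,
    QuantizedImage,
    ThresholdSet,
    multilevel_otsu,
    quantize,
)

__all__ = [
    "RampWeights",
    "ChannelResult",
    "BgiReport",
    "ramp_weights",
    "ramp_filter",
    "compute_bgi",
    "compute_bgi_detail",
    "analyze_image",
    "DEFAULT_N_THRESHOLDS",
    "DEFAULT_CHANNELS",
]

DEFAULT_N_THRESHOLDS = 10
DEFAULT_CHANNELS = (GRAY, RED, GREEN, BLUE)


@dataclass(frozen=True)
class RampWeights:
    """Per-class ramp weights, ordered brightest class -> darkest class.

    With the default spacing the weights run 0, 1/N, 2/N, ..., 1 for N+1
    classes, pinning the endpoints the score's definition demands (a pure
    brightest-class image scores 0, a pure darkest-class image 100).  A
    custom ``denominator`` (e.g. N+1) changes the step size; the first
    weight is always 0.
    """

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.weights)
        if len(w) < 2:
            raise ValueError("need at least 2 ramp weights")
        if w[0] != 0.0:
            raise ValueError("first (brightest-class) ramp weight must be 0")
        if any(b <= a for a, b in zip(w, w[1:])):
            raise ValueError("ramp weights must be strictly increasing")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)


def ramp_weights(n_classes: int, denominator: int | None = None) -> RampWeights:
    """Equally spaced ramp weights for ``n_classes`` classes.

    ``denominator`` defaults to ``n_classes - 1`` so the last (darkest)
    weight is exactly 1.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    den = (n_classes - 1) if denominator is None else int(denominator)
    if den < n_classes - 1:
        raise ValueError("denominator must be >= n_classes - 1")
    return RampWeights(tuple(g / den for g in range(n_classes)))


def ramp_filter(class_counts, weights: RampWeights) -> float:
    """Filtered histogram area A2 = sum of weight[g] * count[g].

    ``class_counts`` must be ordered brightest class -> darkest class to
    match the weight ordering (the darkest class carries the top weight).
    """
    counts = np.asarray(class_counts, dtype=np.float64)
    if counts.ndim != 1 or len(counts) != len(weights):
        raise ValueError(
            f"class_counts length {counts.shape} does not match "
            f"{len(weights)} ramp weights"
        )
    if (counts < 0).any():
        raise ValueError("class counts must be nonnegative")
    return float(counts @ np.asarray(weights.weights))


@dataclass(frozen=True)
class ChannelResult:
    """BGI outcome for one channel: score plus intermediate artifacts."""

    channel_label: str
    bgi: float
    a1: int
    a2: float
    thresholds: ThresholdSet | None
    filtered_counts: tuple[float, ...]  # brightest -> darkest ordering
    quantized: QuantizedImage | None
    degenerate: bool = False


@dataclass(frozen=True)
class BgiReport:
    """Per-channel BGI values with the artifacts needed for export."""

    channels: dict[str, ChannelResult]

    @property
    def bgi(self) -> dict[str, float]:
        return {label: res.bgi for label, res in self.channels.items()}

    @property
    def a1(self) -> int:
        return next(iter(self.channels.values())).a1


def compute_bgi_detail(
    img: RasterImage,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
    thresholds: ThresholdSet | None = None,
    ramp_denominator: int | None = None,
    channel_label: str = GRAY,
    keep_quantized: bool = True,
) -> ChannelResult:
    """Score one channel, returning intermediates alongside the BGI value.

    ``thresholds`` may be supplied to score under a fixed, externally
    chosen partition; otherwise multilevel Otsu is run on the channel's
    histogram.  Channels whose histogram is too flat to threshold (at most
    ``n_thresholds`` distinct intensities — blank or fully saturated
    coupons) are scored by the continuous fallback
    ``BGI = 100 * mean(255 - v) / 255``, which for a uniform intensity v
    reduces to ``100 * (255 - v) / 255``.
    """
    if img.channels != 1:
        raise ValueError("compute_bgi operates on a single channel")
    a1 = img.pixels.size

    if thresholds is None:
        hist = compute_histogram(img, channel_label=channel_label)
        try:
            thresholds = multilevel_otsu(hist, n_thresholds=n_thresholds)
        except DegenerateHistogramError:
            # too few distinct intensities to place the thresholds:
            # score by direct intensity mapping instead
            mean_v = float(img.pixels.mean())
            bgi = 100.0 * (255.0 - mean_v) / 255.0
            return ChannelResult(
                channel_label=channel_label,
                bgi=bgi,
                a1=a1,
                a2=bgi / 100.0 * a1,
                thresholds=None,
                filtered_counts=(),
                quantized=None,
                degenerate=True,
            )

    quant = quantize(img, thresholds)
    weights = ramp_weights(thresholds.n_classes, denominator=ramp_denominator)
    # class_counts() is darkest-first; the ramp is brightest-first
    counts_bright_first = quant.class_counts()[::-1]
    a2 = ramp_filter(counts_bright_first, weights)
    bgi = 100.0 * a2 / a1
    filtered = tuple(
        float(w * c) for w, c in zip(weights.weights, counts_bright_first)
    )
    return ChannelResult(
        channel_label=channel_label,
        bgi=bgi,
        a1=a1,
        a2=a2,
        thresholds=thresholds,
        filtered_counts=filtered,
        quantized=quant if keep_quantized else None,
    )


def compute_bgi(
    img: RasterImage,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
    thresholds: ThresholdSet | None = None,
    ramp_denominator: int | None = None,
) -> float:
    """BGI score (0–100) of a single-channel image."""
    return compute_bgi_detail(
        img,
        n_thresholds=n_thresholds,
        thresholds=thresholds,
        ramp_denominator=ramp_denominator,
        keep_quantized=False,
    ).bgi


def analyze_image(
    img: RasterImage,
    roi: RegionOfInterest | None = None,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
    channels=DEFAULT_CHANNELS,
    gray_weights="luma",
    ramp_denominator: int | None = None,
) -> BgiReport:
    """Full BGI analysis of a colour coupon photograph over a ROI.

    Produces one :class:`ChannelResult` per requested channel (grayscale
    plus red, green, blue by default), each thresholded independently on
    its own histogram.
    """
    if img.channels != 3:
        raise ValueError("analyze_image requires a 3-channel image")
    if roi is None:
        roi = RegionOfInterest.full(img)
    sub = extract_roi(img, roi)
    red, green, blue = split_channels(sub)
    available = {
        GRAY: lambda: to_grayscale(sub, weights=gray_weights),
        RED: lambda: red,
        GREEN: lambda: green,
        BLUE: lambda: blue,
    }
    results: dict[str, ChannelResult] = {}
    for label in channels:
        if label not in available:
            raise ValueError(f"unknown channel {label!r}")
        results[label] = compute_bgi_detail(
            available[label](),
            n_thresholds=n_thresholds,
            ramp_denominator=ramp_denominator,
            channel_label=label,
        )
    return BgiReport(channels=results)
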