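"""Image loading, channel handling, ROI extraction, and histograms.

Every algorithm in this package operates on 8-bit-per-channel rasters of
photographed sample coupons.  This module provides the shared substrate:
a thin validated wrapper over a ``numpy`` pixel grid, explicit rectangular
regions of interest (the analysed area excludes coupon edges, mounting
holes and markings), colour-channel separation, grayscale conversion, and
256-bin intensity histograms.

Coordinates are 0-based and half-open, row-major ``(row, column)``.
Regions of interest are supplied as explicit coordinates rather than
interactively, so every analysis is scriptable and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import imageio.v3 as iio

__all__ = [
    "RasterImage",
    "RegionOfInterest",
    "ChannelHistogram",
    "DecodeError",
    "FormatError",
    "ChannelError",
    "BoundsError",
    "load_image",
    "to_grayscale",
    "split_channels",
    "merge_channels",
    "extract_roi",
    "compute_histogram",
    "GRAY",
    "RED",
    "GREEN",
    "BLUE",
    "LUMA_WEIGHTS",
    "EQUAL_WEIGHTS",
]

GRAY = "gray"
RED = "red"
GREEN = "green"
BLUE = "blue"

#: ITU-R BT.601 luma weights, the standard camera-pipeline convention.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)
#: Plain unweighted channel mean, available via ``gray_weights="equal"``.
EQUAL_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


class DecodeError(ValueError):
    """The file could not be read or decoded as a raster image."""


class FormatError(ValueError):
    """The decoded raster has an unsupported bit depth or channel count."""


class ChannelError(ValueError):
    """An operation received an image with the wrong number of channels."""


class BoundsError(ValueError):
    """A region of interest does not lie within the image."""


@dataclass(frozen=True)
class RasterImage:
    """An 8-bit grayscale or RGB raster.

    Parameters
    ----------
    pixels
        ``(H, W)`` array for grayscale or ``(H, W, 3)`` for RGB, dtype
        ``uint8`` (any integer array within [0, 255] is accepted and cast).
    provenance
        Free-text source label (file path, generator description, ...).
    """

    pixels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3):
            raise FormatError(f"expected 2-D or 3-D pixel grid, got ndim={px.ndim}")
        if px.ndim == 3 and px.shape[2] != 3:
            raise FormatError(f"expected 3 colour channels, got {px.shape[2]}")
        if px.size == 0:
            raise FormatError("image must contain at least one pixel")
        if not np.issubdtype(px.dtype, np.integer):
            raise FormatError(f"pixel dtype must be integer, got {px.dtype}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise FormatError("integer pixel values outside [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else 3

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RasterImage):
            return NotImplemented
        return self.pixels.shape == other.pixels.shape and bool(
            np.array_equal(self.pixels, other.pixels)
        )


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open rectangular pixel range ``[row_start, row_end) x [col_start, col_end)``."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if self.row_start < 0 or self.col_start < 0:
            raise BoundsError("ROI start indices must be nonnegative")
        if self.row_end <= self.row_start or self.col_end <= self.col_start:
            raise BoundsError("ROI must have positive extent (end > start)")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_end - self.row_start, self.col_end - self.col_start)

    @property
    def area(self) -> int:
        h, w = self.shape
        return h * w

    def check_within(self, img: RasterImage) -> None:
        if self.row_end > img.height or self.col_end > img.width:
            raise BoundsError(
                f"ROI {self} exceeds image extent {img.height}x{img.width}"
            )

    @classmethod
    def full(cls, img: RasterImage) -> "RegionOfInterest":
        return cls(0, img.height, 0, img.width)


@dataclass(frozen=True)
class ChannelHistogram:
    """256-bin intensity count vector for one channel over one ROI.

    ``total`` is the ROI pixel count; the sum of ``counts`` always equals it
    (this is the quantity the BGI score calls A1).
    """

    counts: np.ndarray
    channel_label: str = GRAY

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (256,):
            raise ValueError(f"histogram must have 256 bins, got shape {c.shape}")
        if (c < 0).any():
            raise ValueError("histogram counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_nonempty_bins(self) -> int:
        return int(np.count_nonzero(self.counts))


def load_image(path) -> RasterImage:
    """Load a PNG/TIFF/JPEG raster as an 8-bit :class:`RasterImage`.

    Alpha channels are dropped; 16-bit sources are linearly rescaled to
    8-bit (integer division by 257, mapping 65535 -> 255) so that every
    histogram downstream has exactly 256 bins.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio raises plugin-specific errors
        raise DecodeError(f"cannot decode image file {path!r}: {exc}") from exc

    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise FormatError(f"unsupported raster shape {arr.shape} in {path!r}")

    if arr.dtype == np.uint8:
        px = arr
    elif arr.dtype == np.uint16:
        px = (arr // 257).astype(np.uint8)
    elif arr.dtype == bool:
        px = arr.astype(np.uint8) * 255
    else:
        raise FormatError(f"unsupported pixel dtype {arr.dtype} in {path!r}")
    return RasterImage(px, provenance=str(path))


def save_image(img: RasterImage, path) -> None:
    """Write an image as PNG/TIFF for visual inspection."""
    iio.imwrite(path, img.pixels)


def to_grayscale(img: RasterImage, weights="luma") -> RasterImage:
    """Collapse an RGB image to one channel.

    ``weights`` is ``"luma"`` (ITU-R BT.601, default), ``"equal"``
    (plain mean) or an explicit triple summing to 1.  A 1-channel image is
    returned unchanged.  Each output pixel is ``round(wr*R + wg*G + wb*B)``.
    """
    if img.channels == 1:
        return img
    if weights == "luma":
        w = LUMA_WEIGHTS
    elif weights == "equal":
        w = EQUAL_WEIGHTS
    else:
        w = tuple(float(x) for x in weights)
        if len(w) != 3:
            raise ValueError("gray weights must be a triple")
    vals = img.pixels.astype(np.float64) @ np.asarray(w)
    # round half up, deterministically, then clamp
    gray = np.clip(np.floor(vals + 0.5), 0, 255).astype(np.uint8)
    return RasterImage(gray, provenance=img.provenance)


def split_channels(img: RasterImage) -> tuple[RasterImage, RasterImage, RasterImage]:
    """Separate an RGB image into red, green and blue single-channel images."""
    if img.channels != 3:
        raise ChannelError("split_channels requires a 3-channel image")
    return tuple(
        RasterImage(img.pixels[:, :, k].copy(), provenance=img.provenance)
        for k in range(3)
    )


def merge_channels(
    red: RasterImage, green: RasterImage, blue: RasterImage
) -> RasterImage:
    """Inverse of :func:`split_channels`."""
    for ch in (red, green, blue):
        if ch.channels != 1:
            raise ChannelError("merge_channels requires 1-channel inputs")
    if not (red.pixels.shape == green.pixels.shape == blue.pixels.shape):
        raise ChannelError("channel dimensions differ")
    return RasterImage(
        np.stack([red.pixels, green.pixels, blue.pixels], axis=-1),
        provenance=red.provenance,
    )


def extract_roi(img: RasterImage, roi: RegionOfInterest) -> RasterImage:
    """Return the sub-image covering exactly the ROI's half-open ranges."""
    roi.check_within(img)
    sub = img.pixels[roi.row_start : roi.row_end, roi.col_start : roi.col_end]
    return RasterImage(sub.copy(), provenance=img.provenance)


def compute_histogram(img: RasterImage, channel_label: str = GRAY) -> ChannelHistogram:
    """256-bin intensity histogram of a single-channel image."""
    if img.channels != 1:
        raise ChannelError("compute_histogram requires a 1-channel image")
    counts = np.bincount(img.pixels.ravel(), minlength=256)
    return ChannelHistogram(counts, channel_label=channel_label)
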