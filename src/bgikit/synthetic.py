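"""Synthetic stained-coupon photographs and paired control measurements.

Real inputs to this package are photographs of 2.5 x 2.5 cm fiberglass
coupons stained after exposure to a bacterial culture: a green-tinted,
lightly textured substrate overlaid with spatially heterogeneous dark
purple-hued patches of stained biofilm, whose overall darkness grows
with the amount of growth, plus camera sensor noise.  This module
produces such images procedurally so that every pipeline stage is
testable without wet-lab data.

The stain layer is composited multiplicatively (substrate intensity
times a per-channel transmission), so at high growth the channels the
stain absorbs most strongly saturate first — emulating the saturation
seen on heavily fouled coupons.  Blob placement, substrate texture and
sensor noise all derive from a single seed; identical seed and
parameters give bit-identical images, and at a fixed seed the stain
opacity is pixelwise nondecreasing in the growth level.

:func:`generate_growth_series` builds a full experiment: triplicate
coupons at 0, 48, 72 and 144 h, cell density growing exponentially with
multiplicative lognormal replicate noise, image darkness driven by log
cell density, and a paired control table (OD600 and cells/cm^2) in the
format the ranking stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import CELLS_PER_ML_PER_AU
from .raster_core import RasterImage

__all__ = [
    "CouponGrowthParams",
    "GrowthSeriesSpec",
    "CouponSample",
    "generate_coupon_image",
    "generate_growth_series",
]


@dataclass(frozen=True)
class CouponGrowthParams:
    """Appearance controls for one synthetic coupon photograph.

    growth_level
        Dimensionless in [0, 1]; 0 is a clean coupon, 1 fully fouled.
    substrate_tint / stain_tint
        8-bit RGB of the clean fiberglass (greenish) and of fully opaque
        stain (purple-hued).
    blob_count, blob_scale
        Number and characteristic radius (pixels) of the smooth random
        patches that make the biofilm spatially heterogeneous.  Many
        moderately sized patches self-average, keeping the replicate
        scatter of aggregate darkness realistic (a few BGI units).
    weave_amplitude
        Intensity amplitude of the periodic fiberglass weave texture.
    speck_fraction
        Fraction of pixels carrying dark growth-independent specks
        (dust, pores, fibre ends), anchoring the dark end of the
        intensity histogram as real photographs do.
    mottle_amplitude
        Opacity amplitude of the growth-independent residual-stain
        mottle.  Staining leaves a faint large-scale tide mark even on
        clean coupons; it is what makes a binary threshold split the
        bulk of a clean image (areal coverage near 50 % with large
        replicate swings) while the multilevel score stays low and
        stable.
    noise_sd
        Additive Gaussian sensor noise, intensity units.
    """

    growth_level: float
    substrate_tint: tuple[int, int, int] = (168, 186, 152)
    stain_tint: tuple[int, int, int] = (72, 44, 90)
    blob_count: int = 48
    blob_scale: float = 50.0
    weave_amplitude: float = 6.0
    speck_fraction: float = 0.001
    mottle_amplitude: float = 0.18
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.growth_level <= 1.0):
            raise ValueError("growth_level must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for tint in (self.substrate_tint, self.stain_tint):
            if len(tint) != 3 or any(not (0 <= v <= 255) for v in tint):
                raise ValueError(f"tint must be an 8-bit RGB triple: {tint}")
        if self.blob_count < 1 or self.blob_scale <= 0:
            raise ValueError("blob controls must be positive")
        if not (0.0 <= self.speck_fraction <= 0.05):
            raise ValueError("speck_fraction must lie in [0, 0.05]")
        if self.weave_amplitude < 0 or self.mottle_amplitude < 0:
            raise ValueError("texture amplitudes must be nonnegative")


def _blob_field(rng: np.random.Generator, size: int, params: CouponGrowthParams) -> np.ndarray:
    """Smooth random patch field in [0, 1]: sum of Gaussian bumps.

    Normalised by its 95th percentile (then clipped) rather than its
    maximum so the field's scale does not hinge on a single extreme bump.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    f = np.zeros((size, size))
    scale = params.blob_scale * size / 500.0  # radius expressed at the default size
    for _ in range(params.blob_count):
        cy, cx = rng.uniform(0, size, 2)
        sigma = scale * (0.5 + rng.uniform())
        amp = 0.4 + 0.6 * rng.uniform()
        f += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))
    ref = np.percentile(f, 95)
    if ref > 0:
        f = np.clip(f / ref, 0.0, 1.0)
    return f


def generate_coupon_image(params: CouponGrowthParams, size: int = 500) -> RasterImage:
    """Render one synthetic stained-coupon photograph.

    Deterministic given ``params.seed``; the random draws do not depend
    on ``growth_level`` or ``noise_sd``, so varying either at a fixed
    seed changes only the compositing, never the spatial fields.
    """
    if size < 2:
        raise ValueError("image size must be at least 2 px")
    rng = np.random.default_rng(params.seed)

    # substrate: tinted fiberglass with fine texture and a periodic weave
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=2.5)
    texture *= 4.0
    phase = np.arange(size) / 7.0
    weave = params.weave_amplitude * np.outer(np.sin(phase), np.sin(phase))

    # sparse growth-independent dark specks (dust, pores, fibre ends)
    specks = np.zeros((size, size))
    n_specks = int(params.speck_fraction * size * size)
    if n_specks:
        ys = rng.integers(0, size, n_specks)
        xs = rng.integers(0, size, n_specks)
        specks[ys, xs] = rng.uniform(30.0, 120.0, n_specks)
        specks = ndimage.grey_dilation(specks, size=2)

    # residual-stain mottle: faint large-scale tide mark, growth-independent
    mottle = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=size / 10)
    span = np.ptp(mottle)
    mottle = (mottle - mottle.min()) / (span if span else 1.0)

    blobs = _blob_field(rng, size, params)
    sensor_noise = rng.normal(0.0, 1.0, (size, size, 3))

    # stain opacity: residual mottle plus a thin uniform film and patchy
    # accumulation scaled by growth; pixelwise nondecreasing in growth_level
    opacity = np.clip(
        params.mottle_amplitude * mottle
        + params.growth_level * (0.15 + 1.0 * blobs**0.6),
        0.0,
        1.0,
    )

    substrate = np.asarray(params.substrate_tint, dtype=np.float64)
    stain = np.asarray(params.stain_tint, dtype=np.float64)
    # per-channel transmission of the stain layer at full opacity
    transmission = 1.0 - opacity[:, :, None] * (1.0 - stain / 255.0)

    base = substrate[None, None, :] + (texture + weave - specks)[:, :, None]
    img = base * transmission + params.noise_sd * sensor_noise
    px = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return RasterImage(
        px,
        provenance=f"synthetic coupon g={params.growth_level:.3f} seed={params.seed}",
    )


@dataclass(frozen=True)
class GrowthSeriesSpec:
    """Design of a synthetic growth experiment with paired controls.

    Defaults follow the standard assay layout: triplicate coupons at
    0, 48, 72 and 144 h, exponential growth of areal cell density from
    ``base_density_cm2`` with doubling time ``doubling_time_h`` and
    lognormal replicate scatter ``replicate_sigma`` (natural-log sd).
    Image darkness is driven by log10 cell density mapped linearly onto
    growth level across ``density_log_range`` (saturating at 1), so BGI
    tracks log density by construction.
    """

    time_points_h: tuple[float, ...] = (0.0, 48.0, 72.0, 144.0)
    replicates: int = 3
    base_density_cm2: float = 4.0e5
    doubling_time_h: float = 15.0
    replicate_sigma: float = 0.25
    density_log_range: tuple[float, float] = (5.5, 8.5)
    suspension_volume_ml: float = 15.0
    coupon_side_cm: float = 2.5
    n_sides: int = 2
    image_size: int = 500
    stained: bool = True
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.time_points_h)
        if any(b <= a for a, b in zip(t, t[1:])) or len(t) < 1:
            raise ValueError("time points must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.base_density_cm2 <= 0 or self.doubling_time_h <= 0:
            raise ValueError("growth parameters must be positive")
        lo, hi = self.density_log_range
        if hi <= lo:
            raise ValueError("density_log_range must be increasing")
        object.__setattr__(self, "time_points_h", t)


@dataclass(frozen=True)
class CouponSample:
    """One imaged coupon of the synthetic series with its metadata."""

    sample_id: str
    time_h: float
    replicate: int
    growth_level: float
    cells_cm2: float
    image: RasterImage


def _growth_level_from_density(density: float, log_range: tuple[float, float]) -> float:
    lo, hi = log_range
    return float(np.clip((np.log10(density) - lo) / (hi - lo), 0.0, 1.0))


def generate_growth_series(
    spec: GrowthSeriesSpec,
) -> tuple[list[CouponSample], pd.DataFrame]:
    """Build a full synthetic experiment: images plus the control table.

    Returns one :class:`CouponSample` per time point x replicate and a
    tidy control DataFrame with columns ``sample_id, time_h, replicate,
    od600, cells_cm2``.  Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    area = spec.n_sides * spec.coupon_side_cm**2
    samples: list[CouponSample] = []
    records = []
    for t in spec.time_points_h:
        expected = spec.base_density_cm2 * 2.0 ** (t / spec.doubling_time_h)
        for rep in range(1, spec.replicates + 1):
            density = expected * float(
                np.exp(rng.normal(0.0, spec.replicate_sigma))
            )
            g = _growth_level_from_density(density, spec.density_log_range)
            if not spec.stained:
                # unstained coupons barely darken: compress the dynamic range
                g *= 0.06
            img_seed = int(rng.integers(2**31))
            params = CouponGrowthParams(
                growth_level=g, noise_sd=spec.noise_sd, seed=img_seed
            )
            image = generate_coupon_image(params, size=spec.image_size)
            sid = f"t{int(t):03d}_r{rep}"
            od600 = density * area / (CELLS_PER_ML_PER_AU * spec.suspension_volume_ml)
            samples.append(
                CouponSample(
                    sample_id=sid,
                    time_h=t,
                    replicate=rep,
                    growth_level=g,
                    cells_cm2=density,
                    image=image,
                )
            )
            records.append(
                {
                    "sample_id": sid,
                    "time_h": t,
                    "replicate": rep,
                    "od600": od600,
                    "cells_cm2": density,
                }
            )
    return samples, pd.DataFrame.from_records(records)
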