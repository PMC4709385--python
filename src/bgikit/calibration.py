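"""Cell-density control arithmetic and method-ranking statistics.

The independent control for each coupon is the areal cell density of the
biofilm, obtained by sonicating the cells off the coupon into a known
volume of buffer and measuring the suspension's optical density at
600 nm.  In the 0–1 AU range OD600 is roughly proportional to cell
concentration at 3.9e8 cells/mL per absorbance unit; multiplying by the
suspension volume and dividing by the coupon surface (both sides of the
square coupon) gives cells/cm^2.

Image-analysis methods are ranked against this control with a composite
goodness-of-fit score: the Pearson correlation r between the metric
series and the (log10-transformed) control, times the slope m of an
ordinary least-squares fit on min–max normalised scales.  A method that
tracks the control perfectly has r = m = 1 and score 1; the score is
clamped below at 0, so anti-correlated metrics score 0.

Cell density spans orders of magnitude while image metrics are linear,
hence the log10 transform of the control before correlation; zero
densities are floored one decade below the smallest positive observation
so blank samples remain usable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CELLS_PER_ML_PER_AU",
    "OdMeasurement",
    "MethodSeries",
    "MethodFit",
    "UndefinedStatisticError",
    "od_to_cell_concentration",
    "areal_cell_density",
    "log_transform_control",
    "pearson_r",
    "regression_slope",
    "fit_score",
    "rank_methods",
]

#: Cell concentration per absorbance unit of OD600 (cells/mL per AU),
#: valid as a rough proportionality in the 0–1 AU range.
CELLS_PER_ML_PER_AU = 3.9e8


class UndefinedStatisticError(ValueError):
    """A correlation or slope is undefined (constant series, too few points)."""


@dataclass(frozen=True)
class OdMeasurement:
    """One optical-density control measurement and its geometry.

    Defaults match the standard assay: 15 mL of suspension from a
    2.5 x 2.5 cm coupon counted on both sides.
    """

    od600: float
    suspension_volume_ml: float = 15.0
    coupon_side_cm: float = 2.5
    n_sides: int = 2

    def __post_init__(self) -> None:
        if self.od600 < 0:
            raise ValueError("OD600 cannot be negative")
        if self.suspension_volume_ml <= 0:
            raise ValueError("suspension volume must be positive")
        if self.coupon_side_cm <= 0 or self.n_sides < 1:
            raise ValueError("coupon geometry must be positive")


def od_to_cell_concentration(od600: float) -> float:
    """Convert OD600 (AU) to suspended cell concentration (cells/mL)."""
    if od600 < 0:
        raise ValueError("OD600 cannot be negative")
    if od600 > 1:
        warnings.warn(
            "OD600 above 1 AU is outside the linear range of the "
            "absorbance-to-cell-count proportionality",
            stacklevel=2,
        )
    return CELLS_PER_ML_PER_AU * od600


def areal_cell_density(m: OdMeasurement) -> float:
    """Areal biofilm cell density on the coupon (cells/cm^2).

    Total cells dispersed in the suspension divided by the coupon area,
    counted over ``n_sides`` faces of the square coupon.
    """
    area = m.n_sides * m.coupon_side_cm**2
    if area <= 0:
        raise ValueError("coupon area must be positive")
    cells = od_to_cell_concentration(m.od600) * m.suspension_volume_ml
    return cells / area


def log_transform_control(densities, floor: float | None = None) -> np.ndarray:
    """log10 of a cell-density series, flooring nonpositive entries.

    ``floor`` defaults to one decade below the smallest positive value in
    the series (the effective detection floor of the assay), so blank
    samples map to a finite value just below every real observation.
    """
    d = np.asarray(densities, dtype=np.float64)
    positive = d[d > 0]
    if positive.size == 0:
        raise ValueError("control series has no positive densities")
    if floor is None:
        floor = float(positive.min()) / 10.0
    return np.log10(np.maximum(d, floor))


@dataclass(frozen=True)
class MethodSeries:
    """One image metric's values paired sample-by-sample with the control."""

    method_label: str
    values: np.ndarray
    control: np.ndarray  # areal cell density, cells/cm^2
    time_h: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        c = np.asarray(self.control, dtype=np.float64)
        if v.shape != c.shape or v.ndim != 1:
            raise ValueError("values and control must be equal-length 1-D series")
        if v.size < 3:
            raise ValueError("need at least 3 paired samples")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "control", c)
        if self.time_h is not None:
            t = np.asarray(self.time_h, dtype=np.float64)
            if t.shape != v.shape:
                raise ValueError("time_h must align with values")
            object.__setattr__(self, "time_h", t)

    def averaged_by_time(self) -> "MethodSeries":
        """Collapse replicates to per-time-point means (sensitivity option)."""
        if self.time_h is None:
            raise ValueError("time_h required to average by time point")
        times = np.unique(self.time_h)
        v = np.array([self.values[self.time_h == t].mean() for t in times])
        c = np.array([self.control[self.time_h == t].mean() for t in times])
        return MethodSeries(self.method_label, v, c, time_h=times)


@dataclass(frozen=True, order=False)
class MethodFit:
    """Composite fit of one metric against the control: (r, m, score)."""

    method_label: str
    r: float
    m: float
    score: float


def _check_series(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be equal-length 1-D arrays")
    if x.size < 3:
        raise UndefinedStatisticError("need at least 3 paired samples")
    return x, y


def pearson_r(x, y) -> float:
    """Product-moment correlation between two paired series."""
    x, y = _check_series(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)


def _minmax(v: np.ndarray) -> np.ndarray:
    span = np.ptp(v)
    if span == 0:
        raise UndefinedStatisticError("cannot normalise a constant series")
    return (v - v.min()) / span


def regression_slope(x, y) -> float:
    """OLS slope of y on x after min–max normalising both to [0, 1].

    Normalising makes "slope nearest 1" meaningful across metrics with
    different native units (percent coverage, BGI, absorbance).
    """
    x, y = _check_series(x, y)
    return float(stats.linregress(_minmax(x), _minmax(y)).slope)


def fit_score(
    series: MethodSeries,
    control_transform: str = "log10",
    average_by_time: bool = False,
) -> MethodFit:
    """Composite goodness-of-fit of a metric against the cell-density control.

    The control is log10-transformed by default (``control_transform`` in
    {"log10", "linear"}); score = clamp(r * m, 0, 1).
    """
    if average_by_time:
        series = series.averaged_by_time()
    if control_transform == "log10":
        x = log_transform_control(series.control)
    elif control_transform == "linear":
        x = series.control
    else:
        raise ValueError(f"unknown control transform {control_transform!r}")
    r = pearson_r(x, series.values)
    m = regression_slope(x, series.values)
    # best fit needs r and m BOTH near 1: an anti-correlated metric has
    # r < 0 and m < 0, whose raw product would be spuriously positive
    if r <= 0 or m <= 0:
        score = 0.0
    else:
        score = float(min(r * m, 1.0))
    return MethodFit(method_label=series.method_label, r=r, m=m, score=score)


def rank_methods(fits) -> list[MethodFit]:
    """Order fits best-to-worst by score; ties broken alphabetically by label."""
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("ranking needs at least 2 method fits")
    return sorted(fits, key=lambda f: (-f.score, f.method_label))
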