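"""Signal transfer property (STP): dose-response linearity of the detector.

The STP relates the air kerma at the detector plane to the mean pixel value
(MPV) over the detected skin region:

    A_k = d * t              (mean dose rate x exposure time, mGy)
    MPV(A_k) = (1/N) * sum over ROI of p_ij(A_k)

A well-behaved digital detector has a linear STP; here linearity follows the
standard criterion that no experimental point deviates more than 2 % from
the fitted line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import CorrectedImage, RoiMask

__all__ = [
    "DoseMeasurement",
    "StpPoint",
    "StpFit",
    "air_kerma",
    "mean_pixel_value",
    "linear_fit",
    "fit_stp",
    "stp_slope_table",
]

#: Maximum relative deviation from the fitted line for a linear detector.
LINEARITY_TOLERANCE = 0.02


@dataclass(frozen=True)
class DoseMeasurement:
    """Air kerma derived from repeated dose-rate readings."""

    dose_rates_mgy_s: tuple[float, ...]
    exposure_s: float
    air_kerma_mgy: float


@dataclass(frozen=True)
class StpPoint:
    """One dose-response point: air kerma vs ROI mean pixel value."""

    air_kerma: float
    mpv: float
    mpv_sd: float = 0.0


@dataclass(frozen=True)
class StpFit:
    """Ordinary-least-squares dose-response fit and linearity verdict."""

    slope: float
    intercept: float
    r_squared: float
    max_relative_deviation: float
    is_linear: bool
    slope_stderr: float = float("nan")
    relative_deviations: tuple[float, ...] = ()


def air_kerma(
    dose_rates: Sequence[float], exposure_s: float, *, require_five: bool = True
) -> DoseMeasurement:
    """Air kerma as the product of the mean dose rate and exposure time.

    The measurement protocol averages the dose rate over five readings;
    pass ``require_five=False`` to accept a different count.
    """
    rates = tuple(float(r) for r in dose_rates)
    if require_five and len(rates) != 5:
        raise ValueError(
            f"expected exactly five dose-rate readings, got {len(rates)} "
            "(pass require_five=False to override)"
        )
    if not rates:
        raise ValueError("at least one dose-rate reading is required")
    if any(r < 0 for r in rates):
        raise ValueError("dose rates must be non-negative")
    if exposure_s <= 0:
        raise ValueError("exposure time must be positive")
    return DoseMeasurement(
        dose_rates_mgy_s=rates,
        exposure_s=float(exposure_s),
        air_kerma_mgy=float(np.mean(rates)) * float(exposure_s),
    )


def mean_pixel_value(
    image: "CorrectedImage | np.ndarray", roi: RoiMask | None = None
) -> float:
    """Mean pixel value over the detected region of interest.

    Accepts either a :class:`~skinqa.preprocessing.CorrectedImage` (whose
    own ROI is used) or a plain 2-D image with an explicit ``roi``.
    """
    if isinstance(image, CorrectedImage):
        values = image.roi_values()
    else:
        if roi is None:
            raise ValueError("a RoiMask is required for a plain image")
        image = np.asarray(image, dtype=np.float64)
        if image.shape != roi.mask.shape:
            raise ValueError("image and ROI dimensions differ")
        values = image[roi.mask]
    if values.size == 0:
        raise ValueError("ROI is empty")
    return float(values.mean())


def linear_fit(x: np.ndarray, y: np.ndarray):
    """Unweighted OLS line fit; errors on a degenerate abscissa.

    Returns the :mod:`scipy.stats` linregress result.  Shared by the STP
    fit and the stretch-trend fit.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa: all x values are equal")
    return stats.linregress(x, y)


def fit_stp(points: Sequence[StpPoint]) -> StpFit:
    """OLS fit of MPV vs air kerma with the 2 % linearity criterion.

    The relative deviation of each point is measured against the fitted
    value; the detector is flagged linear iff the maximum deviation is at
    most 2 %.  R^2 is the standard coefficient of determination.
    """
    if len(points) < 3:
        raise ValueError("at least three dose points are required")
    x = np.array([p.air_kerma for p in points])
    y = np.array([p.mpv for p in points])
    if len(np.unique(x)) < 3:
        raise ValueError("at least three distinct air-kerma values are required")
    res = linear_fit(x, y)
    fitted = res.slope * x + res.intercept
    if np.any(fitted == 0):
        raise ValueError("fitted value of zero: relative deviation undefined")
    rel_dev = np.abs(y - fitted) / np.abs(fitted)
    max_dev = float(rel_dev.max())
    return StpFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        max_relative_deviation=max_dev,
        is_linear=max_dev <= LINEARITY_TOLERANCE,
        slope_stderr=float(res.stderr),
        relative_deviations=tuple(float(d) for d in rel_dev),
    )


def stp_slope_table(
    series_by_cell: Mapping[tuple, Sequence[Sequence[StpPoint]]],
) -> pd.DataFrame:
    """STP slopes across detector variants, with across-replicate error.

    ``series_by_cell`` maps a (thickness, ratio, voltage) key to one or
    more replicate STP series.  Each cell reports the mean of the
    per-replicate fitted slopes and their standard deviation (zero for a
    single replicate), plus the minimum per-replicate R^2.
    """
    rows = []
    for key, replicates in series_by_cell.items():
        if not replicates:
            raise ValueError(f"cell {key!r} has no replicate series")
        fits = [fit_stp(points) for points in replicates]
        slopes = np.array([f.slope for f in fits])
        rows.append(
            {
                "thickness_mm": key[0],
                "ratio": key[1],
                "voltage_kvp": key[2],
                "slope": float(slopes.mean()),
                "slope_sd": float(slopes.std(ddof=0)) if len(slopes) > 1 else 0.0,
                "n_replicates": len(fits),
                "min_r_squared": float(min(f.r_squared for f in fits)),
            }
        )
    return pd.DataFrame(rows).set_index(["thickness_mm", "ratio", "voltage_kvp"])
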