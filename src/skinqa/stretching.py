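"""Stretch-series analysis of the imaging skin.

Stretching the skin increases its in-plane area while thinning it; assuming
volume conservation, the thickness at each elongation step is estimated
from the detected ROI areas as ``t = t0 * A0 / A``.  The module tracks how
the mean pixel value and spatial-frequency response evolve with elongation
(OLS trend fits), quantifies drift of the within-ROI intensity distribution
with the Bhattacharyya distance on mean-removed histograms, and partitions
the ROI into concentric border zones to check that the particle
redistribution stays locally consistent away from the border.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocessing import RoiMask, average_frames, detect_skin_roi
from .stp import linear_fit, mean_pixel_value

__all__ = [
    "StretchState",
    "DistributionComparison",
    "TrendFit",
    "elongation",
    "thickness_volume_conserved",
    "area_ratio_from_rois",
    "mean_removed_histogram",
    "joint_histogram_range",
    "bhattacharyya_distance",
    "compare_histograms",
    "trend_vs_elongation",
    "zone_partition",
    "analyse_stretch_series",
]


@dataclass(frozen=True)
class StretchState:
    """Geometry of one elongation step.

    Volume conservation ties the fields together:
    ``thickness_est_mm * area_ratio == t0_mm`` exactly.
    """

    L0_mm: float
    L_mm: float
    elongation_pct: float
    t0_mm: float
    area_ratio: float
    thickness_est_mm: float

    @classmethod
    def from_lengths(
        cls, L0_mm: float, L_mm: float, t0_mm: float, area_ratio: float
    ) -> "StretchState":
        return cls(
            L0_mm=L0_mm,
            L_mm=L_mm,
            elongation_pct=elongation(L0_mm, L_mm),
            t0_mm=t0_mm,
            area_ratio=area_ratio,
            thickness_est_mm=thickness_volume_conserved(t0_mm, area_ratio),
        )


@dataclass(frozen=True)
class DistributionComparison:
    """Bhattacharyya comparison of two normalised histograms.

    ``disjoint_mass`` is the probability mass living in bins occupied by
    only one of the two histograms; a fully disjoint support gives an
    infinite distance, flagged by ``disjoint``.
    """

    bhattacharyya: float
    disjoint_mass: float
    disjoint: bool


@dataclass(frozen=True)
class TrendFit:
    """OLS trend of a metric vs elongation percent."""

    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float = float("nan")
    degenerate: bool = False


def elongation(L0_mm: float, L_mm: float) -> float:
    """Elongation percent, (L - L0) / L0 * 100.

    Compression (L < L0) is rejected: the stretch rig only pulls.
    """
    if L0_mm <= 0:
        raise ValueError("initial length must be positive")
    if L_mm < L0_mm:
        raise ValueError("stretched length is below the initial length")
    return (L_mm - L0_mm) / L0_mm * 100.0


def thickness_volume_conserved(t0_mm: float, area_ratio: float) -> float:
    """Thickness estimate under volume conservation, t0 / area_ratio."""
    if t0_mm <= 0:
        raise ValueError("initial thickness must be positive")
    if area_ratio < 1:
        raise ValueError(
            "area ratio below 1: the skin cannot shrink under tension"
        )
    return t0_mm / area_ratio


def area_ratio_from_rois(roi0: RoiMask, roi: RoiMask) -> float:
    """Detected-area ratio of a stretched ROI to the initial ROI."""
    if roi0.area_px == 0 or roi.area_px == 0:
        raise ValueError("ROI masks must be non-empty")
    return roi.area_px / roi0.area_px


def joint_histogram_range(*value_sets: np.ndarray) -> tuple[float, float]:
    """Common (min, max) range across mean-removed value sets."""
    lo = min(float(np.min(v)) for v in value_sets)
    hi = max(float(np.max(v)) for v in value_sets)
    if hi <= lo:
        raise ValueError("degenerate range: max equals min")
    return lo, hi


def mean_removed_histogram(
    image: np.ndarray,
    roi: RoiMask,
    n_bins: int = 256,
    value_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Normalised histogram of ROI pixels after subtracting the ROI mean.

    Removing the mean makes the comparison insensitive to the overall
    signal decline with stretch, isolating changes in distribution shape.
    When comparing two images, pass a shared ``value_range`` computed over
    both mean-removed value sets (:func:`joint_histogram_range`).
    """
    image = np.asarray(image, dtype=np.float64)
    values = image[roi.mask]
    if values.size == 0:
        raise ValueError("ROI is empty")
    values = values - values.mean()
    if value_range is None:
        if values.max() <= values.min():
            raise ValueError("degenerate range: constant image")
        value_range = (float(values.min()), float(values.max()))
    elif value_range[1] <= value_range[0]:
        raise ValueError("degenerate range: max equals min")
    hist, _ = np.histogram(values, bins=n_bins, range=value_range)
    total = hist.sum()
    if total == 0:
        raise ValueError("all values fall outside the requested range")
    return hist / total


def bhattacharyya_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Bhattacharyya distance -ln(sum sqrt(p_i q_i)) between histograms.

    Zero for identical distributions; +inf for disjoint supports.  Inputs
    must be normalised to sum 1 over equal bin counts.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("histograms must have equal bin counts")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("histograms must be non-negative")
    for name, h in (("p", p), ("q", q)):
        if abs(h.sum() - 1.0) > 1e-6:
            raise ValueError(f"histogram {name} is not normalised to sum 1")
    bc = float(np.sqrt(p * q).sum())
    if bc <= 0.0:
        return float("inf")
    return max(0.0, -np.log(min(bc, 1.0)))


def compare_histograms(p: np.ndarray, q: np.ndarray) -> DistributionComparison:
    """Bhattacharyya distance plus the mass on non-shared bins."""
    dist = bhattacharyya_distance(p, q)
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    disjoint_mass = float(p[q == 0].sum() + q[p == 0].sum())
    return DistributionComparison(
        bhattacharyya=dist,
        disjoint_mass=disjoint_mass,
        disjoint=not np.isfinite(dist),
    )


def trend_vs_elongation(
    elongations_pct: Sequence[float], metric_values: Sequence[float]
) -> TrendFit:
    """OLS fit of a metric (MPV, SFR50, SFR10, ...) vs elongation percent.

    A constant metric has undefined R^2; it is reported as 0 with the
    ``degenerate`` flag set and a zero slope.
    """
    x = np.asarray(elongations_pct, dtype=np.float64)
    y = np.asarray(metric_values, dtype=np.float64)
    if x.size < 3:
        raise ValueError("at least three elongation steps are required")
    if np.ptp(y) == 0:
        return TrendFit(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, degenerate=True
        )
    res = linear_fit(x, y)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        slope_stderr=float(res.stderr),
    )


def zone_partition(roi: RoiMask, n_zones: int) -> list[np.ndarray]:
    """Partition the ROI into concentric border zones.

    Zones are percentile bands of the Euclidean distance to the ROI border
    (zone 0 hugs the border, the last zone is the core); they are pairwise
    disjoint and their union is exactly the ROI, so per-zone statistics
    track how the border region evolves relative to the bulk.
    """
    if n_zones < 1:
        raise ValueError("n_zones must be at least 1")
    mask = roi.mask
    if n_zones == 1:
        return [mask.copy()]
    dist = ndimage.distance_transform_edt(mask)
    vals = dist[mask]
    edges = np.quantile(vals, np.linspace(0.0, 1.0, n_zones + 1))
    if np.any(np.diff(edges) <= 0):
        raise ValueError("ROI too small for the requested number of zones")
    zone_idx = np.clip(
        np.searchsorted(edges[1:-1], vals, side="right"), 0, n_zones - 1
    )
    zones = []
    for z in range(n_zones):
        zmask = np.zeros_like(mask)
        zmask[mask] = zone_idx == z
        if not zmask.any():
            raise ValueError("ROI too small for the requested number of zones")
        zones.append(zmask)
    return zones


def analyse_stretch_series(
    series,
    *,
    n_bins: int = 256,
    full_scale: float = 4095.0,
    min_area_px: int = 64,
) -> tuple[pd.DataFrame, dict[str, TrendFit]]:
    """Per-step stretch table and MPV trend for a simulated stretch series.

    For each elongation step the stack is averaged and dark-corrected, the
    skin ROI re-detected (the skin moves and grows between steps), and the
    table reports MPV, the detected-area ratio versus step 0, the
    volume-conserved thickness estimate, and the Bhattacharyya distance of
    the mean-removed intensity histogram versus step 0 over their joint
    range.

    ``series`` is a :class:`~skinqa.synthetic.StretchSeries` or any object
    with ``steps`` (each bearing ``elongation_pct`` and ``stack``), a
    ``dark`` stack and ``t0_mm``.
    """
    dark_mean = average_frames(series.dark)
    records = []
    base_values = None
    base_roi = None
    rois = []
    images = []
    for step in series.steps:
        img = average_frames(step.stack) - dark_mean
        roi = detect_skin_roi(
            img, np.zeros_like(img), full_scale=full_scale, min_area_px=min_area_px
        )
        rois.append(roi)
        images.append(img)
    base_roi = rois[0]
    base_values = images[0][base_roi.mask]
    base_values = base_values - base_values.mean()

    for step, roi, img in zip(series.steps, rois, images):
        vals = img[roi.mask]
        centred = vals - vals.mean()
        rng = joint_histogram_range(base_values, centred)
        p = mean_removed_histogram(images[0], base_roi, n_bins, rng)
        q = mean_removed_histogram(img, roi, n_bins, rng)
        ratio = area_ratio_from_rois(base_roi, roi)
        records.append(
            {
                "elongation_pct": step.elongation_pct,
                "mpv": mean_pixel_value(img, roi),
                "mpv_sd": float(vals.std(ddof=0)),
                "area_ratio": ratio,
                "thickness_est_mm": thickness_volume_conserved(
                    series.t0_mm, max(ratio, 1.0)
                ),
                "bhattacharyya_vs_0": bhattacharyya_distance(p, q),
            }
        )
    table = pd.DataFrame.from_records(records)
    trends = {
        "mpv": trend_vs_elongation(table["elongation_pct"], table["mpv"]),
    }
    return table, trends
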