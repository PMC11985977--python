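"""Frame averaging, deformable-skin ROI detection, and flat-field correction.

The imaging skin is a stretchable scintillator that can move, deform and
change size between acquisitions, so unlike a conventional flat-panel
detector the usable region of each camera frame must be re-detected.  The
pipeline is:

1. average the buffered frames of each stack (raw / flat / dark),
2. detect the bright skin region on the dark-corrected flat image,
3. apply gain/offset correction restricted to that region::

       corrected = (raw - dark) / (flat - dark) * m,
       m = mean over ROI of (flat - dark)

Pixels outside the detected region are never assigned a numeric value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .config import DetectorConfig

logger = logging.getLogger(__name__)

__all__ = [
    "FrameStack",
    "RoiMask",
    "CorrectedImage",
    "NoSkinError",
    "average_frames",
    "detect_skin_roi",
    "flat_field_correct",
]


class NoSkinError(RuntimeError):
    """No connected bright region above the minimum area was found."""


@dataclass
class FrameStack:
    """A set of co-registered monochrome frames plus acquisition metadata.

    Frames are stored as float64 DN so that synthetic noiseless stacks are
    exact; quantisation to integers happens only when writing TIFF.
    """

    frames: np.ndarray  # (n_frames, H, W)
    config: DetectorConfig = field(default_factory=DetectorConfig)
    label: str = "raw"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) array")
        if self.frames.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if self.frames.min() < 0 or self.frames.max() > self.config.full_scale:
            raise ValueError("pixel values must lie in [0, full_scale]")
        if self.label not in ("raw", "flat", "dark"):
            raise ValueError("label must be one of raw/flat/dark")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class RoiMask:
    """Boolean mask of the detected imaging-skin region.

    ``contour`` holds the ordered (row, col) boundary coordinates of the
    single connected foreground component.
    """

    mask: np.ndarray
    contour: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        n_comp = measure.label(self.mask, connectivity=2).max()
        if n_comp != 1:
            raise ValueError(
                f"RoiMask must have exactly one connected component, got {n_comp}"
            )

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class CorrectedImage:
    """Gain/offset-corrected image, defined only inside the ROI.

    ``pixels`` is NaN outside the ROI; use :meth:`roi_values` for statistics.
    """

    pixels: np.ndarray
    m: float
    roi: RoiMask

    def __post_init__(self) -> None:
        inside = self.pixels[self.roi.mask]
        if not np.all(np.isfinite(inside)):
            raise ValueError("corrected values inside ROI must be finite")

    def roi_values(self) -> np.ndarray:
        """Flat array of corrected values inside the ROI."""
        return self.pixels[self.roi.mask]


def average_frames(stack: FrameStack) -> np.ndarray:
    """Per-pixel arithmetic mean of a stack, as float64 (no truncation)."""
    if stack.n_frames < 1:
        raise ValueError("cannot average an empty stack")
    return stack.frames.mean(axis=0)


def detect_skin_roi(
    flat_mean: np.ndarray,
    dark_mean: np.ndarray,
    *,
    full_scale: float = 4095.0,
    min_area_px: int = 64,
    closing_size: int = 3,
    border_erosion_px: int = 0,
) -> RoiMask:
    """Detect the bright imaging-skin region on the dark-corrected flat image.

    The flat should have been acquired at the highest dose of the session so
    the skin-background contrast is maximal.  The detection chain is:
    Otsu threshold on (flat - dark) -> morphological closing -> largest
    connected component -> hole filling, with pixels whose flat - dark
    difference falls below ``full_scale * 1e-4`` excluded to protect the
    later division.

    Parameters
    ----------
    border_erosion_px:
        Optional erosion of the mask border, to discard the zone near the
        skin edge where optical effects can bias statistics.

    Raises
    ------
    NoSkinError
        If no connected component above ``min_area_px`` survives.
    """
    flat_mean = np.asarray(flat_mean, dtype=np.float64)
    dark_mean = np.asarray(dark_mean, dtype=np.float64)
    if flat_mean.shape != dark_mean.shape:
        raise ValueError("flat and dark images must share dimensions")
    diff = flat_mean - dark_mean
    if diff.max() <= diff.min():
        raise NoSkinError("no skin detected: image has no contrast")

    thr = threshold_otsu(diff)
    # Otsu's histogram-binned threshold can land inside the background mode
    # when the background collapses into a single bin; refine it with
    # intermeans (Ridler-Calvard) iterations, which converge to the midpoint
    # between the class means.
    for _ in range(100):
        lo, hi = diff[diff <= thr], diff[diff > thr]
        if lo.size == 0 or hi.size == 0:
            break
        new = 0.5 * (lo.mean() + hi.mean())
        if abs(new - thr) < 1e-9:
            break
        thr = new
    fg = diff > thr
    if closing_size > 1:
        fg = morphology.closing(fg, morphology.footprint_rectangle(
            (closing_size, closing_size)))

    eps = full_scale * 1e-4
    fg &= diff > eps
    fg = _largest_component(fg)
    fg = ndimage.binary_fill_holes(fg)
    # exclusion of near-dead pixels may re-open holes inside the filled mask
    fg &= diff > eps
    fg = _largest_component(fg)
    if border_erosion_px > 0:
        fg = morphology.erosion(
            fg, morphology.footprint_rectangle(
                (2 * border_erosion_px + 1, 2 * border_erosion_px + 1)))
        fg = _largest_component(fg)

    if fg.sum() < min_area_px:
        raise NoSkinError(
            f"no skin detected: largest component has {int(fg.sum())} px "
            f"(minimum {min_area_px})"
        )
    contour = _closed_contour(fg)
    return RoiMask(mask=fg, contour=contour)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask, connectivity=2)
    n = labels.max()
    if n == 0:
        return mask
    if n > 1:
        logger.info("ROI detection found %d components; keeping the largest", n)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def _closed_contour(mask: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise NoSkinError("no skin detected: empty contour")
    return max(contours, key=len)


def flat_field_correct(
    raw_mean: np.ndarray,
    dark_mean: np.ndarray,
    flat_mean: np.ndarray,
    roi: RoiMask,
    *,
    full_scale: float = 4095.0,
) -> CorrectedImage:
    """Gain/offset correction restricted to the detected skin region.

    Inside the ROI the corrected value is ``(raw - dark) / (flat - dark) * m``
    with ``m`` the ROI mean of ``flat - dark``; outside it is NaN (invalid).

    Raises
    ------
    ValueError
        If ``flat - dark`` is at or below the dead-pixel threshold anywhere
        inside the ROI (such pixels should have been excluded at detection).
    """
    raw_mean = np.asarray(raw_mean, dtype=np.float64)
    dark_mean = np.asarray(dark_mean, dtype=np.float64)
    flat_mean = np.asarray(flat_mean, dtype=np.float64)
    if not (raw_mean.shape == dark_mean.shape == flat_mean.shape == roi.mask.shape):
        raise ValueError("raw, dark, flat and ROI must share dimensions")

    gain = flat_mean - dark_mean
    eps = full_scale * 1e-4
    inside = roi.mask
    if np.any(gain[inside] <= eps):
        raise ValueError(
            "flat - dark <= epsilon inside ROI; re-detect the ROI to exclude "
            "dead pixels before correcting"
        )
    m = float(gain[inside].mean())
    out = np.full(raw_mean.shape, np.nan)
    out[inside] = (raw_mean[inside] - dark_mean[inside]) / gain[inside] * m
    return CorrectedImage(pixels=out, m=m, roi=roi)
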