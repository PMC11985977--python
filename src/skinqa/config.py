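"""Detector acquisition configuration.

The defaults describe the optical stack used throughout the package: a
monochrome scientific CMOS camera imaging the scintillating skin through a
fixed lens, giving an effective pixel pitch of 51 um at the skin plane,
10 buffered frames averaged per acquisition, and a 12-bit signal range
stored in 16-bit containers.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DetectorConfig:
    """Acquisition geometry and digitisation parameters.

    Parameters
    ----------
    pixel_pitch_mm:
        Effective image pixel pitch at the skin plane, in mm.
    n_frames:
        Number of buffered frames averaged per acquisition.
    exposure_ms:
        Exposure time per frame, in milliseconds.
    bit_depth:
        Bit depth of the storage container.
    full_scale:
        Maximum representable pixel value (12-bit signal range by default,
        stored in 16-bit TIFF containers).
    """

    pixel_pitch_mm: float = 0.051
    n_frames: int = 10
    exposure_ms: float = 100.0
    bit_depth: int = 16
    full_scale: float = 4095.0

    def __post_init__(self) -> None:
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0 < self.full_scale <= 2 ** self.bit_depth - 1):
            raise ValueError(
                "full_scale must satisfy 0 < full_scale <= 2**bit_depth - 1"
            )
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")

    @property
    def nyquist_lp_per_mm(self) -> float:
        """Detector Nyquist frequency, 1 / (2 * pixel pitch), in lp/mm."""
        return 1.0 / (2.0 * self.pixel_pitch_mm)
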