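"""Reading and writing of frame stacks and analysis artifacts.

Stacks travel as multi-page 16-bit grayscale TIFF with a JSON sidecar
carrying acquisition metadata (scene parameters, seed, air kerma); corrected
images as 32-bit float TIFF; ROI masks as PNG; contours and curves as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import tifffile

from .config import DetectorConfig
from .preprocessing import CorrectedImage, FrameStack, RoiMask

__all__ = [
    "write_stack",
    "read_stack",
    "write_corrected",
    "write_roi",
    "write_json",
    "read_json",
]


def write_stack(stack: FrameStack, path: "str | Path", metadata: dict | None = None) -> Path:
    """Write a stack as multi-page uint16 TIFF plus a JSON sidecar."""
    path = Path(path)
    data = np.clip(np.rint(stack.frames), 0, stack.config.full_scale).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "label": stack.label,
        "n_frames": stack.n_frames,
        "config": {
            "pixel_pitch_mm": stack.config.pixel_pitch_mm,
            "n_frames": stack.config.n_frames,
            "exposure_ms": stack.config.exposure_ms,
            "bit_depth": stack.config.bit_depth,
            "full_scale": stack.config.full_scale,
        },
    }
    if metadata:
        sidecar.update(metadata)
    write_json(sidecar, path.with_suffix(".json"))
    return path


def read_stack(path: "str | Path", config: DetectorConfig | None = None) -> FrameStack:
    """Read a multi-page TIFF stack; sidecar metadata is used if present."""
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    label = "raw"
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = read_json(sidecar)
        label = meta.get("label", "raw")
        if config is None and "config" in meta:
            config = DetectorConfig(**meta["config"])
    return FrameStack(frames=frames, config=config or DetectorConfig(), label=label)


def write_corrected(image: CorrectedImage, path: "str | Path") -> Path:
    """Write a corrected image as 32-bit float TIFF (NaN outside the ROI)."""
    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    return path


def write_roi(roi: RoiMask, mask_path: "str | Path", contour_path: "str | Path") -> None:
    """Write the ROI as a PNG mask and its contour as a CSV of (row, col)."""
    iio.imwrite(Path(mask_path), (roi.mask * np.uint8(255)), extension=".png")
    np.savetxt(
        Path(contour_path),
        roi.contour,
        delimiter=",",
        header="row,col",
        comments="",
        fmt="%.3f",
    )


def write_json(obj: dict[str, Any], path: "str | Path") -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: "str | Path") -> dict[str, Any]:
    return json.loads(Path(path).read_text())
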