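import numpy as np
import pytest

from skinqa.config import DetectorConfig
from skinqa.preprocessing import RoiMask
from skinqa.synthetic import SyntheticScene, rectangle_polygon


@pytest.fixture
def config() -> DetectorConfig:
    return DetectorConfig()


@pytest.fixture
def small_scene() -> SyntheticScene:
    """120x120 frame with a 100x100 skin; cheap enough for unit tests."""
    return SyntheticScene(
        shape_px=(120, 120),
        skin_polygon=rectangle_polygon(9.5, 9.5, 100, 100),
        response_slope=3000.0,
        response_offset=100.0,
    )


@pytest.fixture
def noiseless_scene(small_scene) -> SyntheticScene:
    import dataclasses

    return dataclasses.replace(small_scene, read_noise_sd=0.0, poisson_scale=None)


@pytest.fixture
def full_roi() -> "callable":
    """Factory for an all-true rectangular ROI of a given shape."""

    def make(shape):
        mask = np.ones(shape, dtype=bool)
        contour = np.array([[0.0, 0.0]])
        return RoiMask(mask=mask, contour=contour)

    return make
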