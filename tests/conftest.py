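import numpy as np
import pytest

from cropseg.geo_io import FieldImage, FieldMask, GeoTransform
from cropseg.synthetic import SceneSpec, make_scene


@pytest.fixture(scope="session")
def small_scene():
    """A compact 3x4-plot optical scene at 17 degrees, with its AOI and truth."""
    spec = SceneSpec(rows=3, cols=4, angle_deg=17.0, seed=1)
    image, aoi, truth = make_scene(spec)
    return spec, image, aoi, truth


@pytest.fixture(scope="session")
def standard_scene():
    """The full 6x10-plot study scene at 17 degrees (seed 1)."""
    spec = SceneSpec(angle_deg=17.0, seed=1)
    image, aoi, truth = make_scene(spec)
    return spec, image, aoi, truth


@pytest.fixture
def unit_grid():
    """1 m pixel grid, origin (0, 100), north-up: map y = 100 - row."""
    return GeoTransform(0.0, 100.0, 1.0, -1.0)


@pytest.fixture
def full_mask():
    def make(shape):
        return FieldMask(np.ones(shape, dtype=bool))

    return make
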