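import numpy as np
import pytest

from tsvf.raster_timeseries import TimeSeriesCube, default_grid
from tsvf.synthetic_scene import SceneConfig, draw_samples, generate


@pytest.fixture(scope="session")
def small_scene():
    """64 x 64 default-condition scene, enough pixels for sampling tests."""
    return generate(SceneConfig(seed=0, width=64, height=64))


@pytest.fixture(scope="session")
def small_samples(small_scene):
    return draw_samples(small_scene, n_validate_per_class=60)


def make_cube(T=3, H=4, W=5, bands=("B2", "B3", "B4", "B8"), seed=0, low=0.05, high=0.6):
    """Small random reflectance cube for unit tests."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(low, high, size=(T, len(bands), H, W))
    dates = [f"2020-{m:02d}-15" for m in range(1, T + 1)]
    return TimeSeriesCube(values=values, band_names=list(bands), dates=dates, grid=default_grid(W, H))


@pytest.fixture
def tiny_cube():
    return make_cube()
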