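import numpy as np
import pytest

from quadmosaic.image_io import CentroidSet, RasterImage
from quadmosaic.synthetic import MosaicSpec, generate_mosaic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    return RasterImage(rng.uniform(0, 255, (32, 32)))


@pytest.fixture(scope="session")
def default_mosaic():
    """One standard ~100-cell fixture, shared across tests (read-only)."""
    return generate_mosaic(MosaicSpec(seed=1))


@pytest.fixture
def small_mosaic():
    return generate_mosaic(MosaicSpec(size=96, hex_pitch=24.0, seed=3, noise_sd=0.5))


@pytest.fixture
def grid_centroids():
    pts = np.array([[3.5, 4.5], [10.0, 10.0], [20.25, 5.75]])
    return CentroidSet(pts, labels=["cone", "rod", "any"], source="manual")
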