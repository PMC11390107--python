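import numpy as np
import pytest

from cvdscreen.fixtures import (
    CONFUSABLE_PALETTES,
    FRIENDLY_PALETTES,
    FixtureSpec,
    make_fixture,
    make_labeled_corpus,
)
from cvdscreen.image import RasterImage


@pytest.fixture(scope="session")
def small_corpus():
    """30 certified fixtures, 20% problematic; shared across tests."""
    return make_labeled_corpus(30, 0.2, seed=42)


@pytest.fixture(scope="session")
def confusable_fixture():
    return make_fixture(FixtureSpec("confusable_blocks", palette=CONFUSABLE_PALETTES[0]))


@pytest.fixture(scope="session")
def friendly_fixture():
    return make_fixture(FixtureSpec("friendly_blocks", palette=FRIENDLY_PALETTES[0]))


@pytest.fixture(scope="session")
def grayscale_fixture():
    return make_fixture(FixtureSpec("grayscale"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def raster_from_colors(colors, shape=None):
    """Build a RasterImage from a nested list of 8-bit color tuples."""
    arr = np.asarray(colors, dtype=np.uint8)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return RasterImage.from_uint8(arr)
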