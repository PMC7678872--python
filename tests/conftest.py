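import numpy as np
import pytest

import alphaflash as af


@pytest.fixture(scope="session")
def acq():
    return af.AcquisitionParams()


@pytest.fixture(scope="session")
def model():
    return af.DoseResponseModel()


@pytest.fixture(scope="session")
def square30():
    """Solid 30x30 footprint -> exactly a 3x3 grid of 10x10 squares."""
    return af.CellGeometry(np.ones((30, 30), dtype=bool))


def make_flash_movie(
    events,
    geometry,
    acq,
    n_frames=120,
    flash=None,
    noise=None,
    seed=0,
):
    """Render a (by default noise-free) movie from explicit events."""
    flash = flash or af.FlashParams()
    noise = noise or af.NoiseParams.noiseless()
    return af.render_movie(events, geometry, acq, flash, noise, n_frames, seed)


@pytest.fixture(scope="session")
def flash_movie_factory():
    return make_flash_movie
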