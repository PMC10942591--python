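import numpy as np
import pytest

from piezomech.model import DEFAULT_GRID, DEFAULT_PARAMS


@pytest.fixture(scope="session")
def params():
    """Default synthetic study conditions (sigma = 50 pN/um)."""
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def grid():
    """Default spectral grid (fs = 19.91 Hz, 2048 frames)."""
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def height_stack(params, grid):
    """A shared 32-pixel membrane height simulation (expensive-ish)."""
    import warnings

    from piezomech import fluctsim

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fluctsim.simulate_height_series(params, grid, n_pixels=32,
                                               seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
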