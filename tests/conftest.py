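import numpy as np
import pytest
from hypothesis import settings

from lifhsi import make_wavelength_grid
from lifhsi.phantom import PhantomConfig, render_scene

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid128():
    """The instrument convention: 128 uniform bands, 400-1000 nm inclusive."""
    return make_wavelength_grid(400.0, 1000.0, 128)


@pytest.fixture(scope="session")
def small_scene():
    """An 80x80 phantom used by unit tests that need a full scene."""
    return render_scene(PhantomConfig(rows=80, cols=80, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
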