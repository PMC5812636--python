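import numpy as np
import pytest

import myofuse as mf


@pytest.fixture(scope="session")
def default_params():
    return mf.SimulationParams()


@pytest.fixture(scope="session")
def day7_scene(default_params):
    """One mid-differentiation scene with ground truth, shared across tests."""
    return mf.simulate_scene(default_params, day=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_image(pixels, channel="cytoplasm", bit_depth=16):
    return mf.Image2D(np.asarray(pixels), bit_depth, channel)


def make_uniform_image(shape=(64, 64), value=0, channel="nucleus", bit_depth=16):
    return make_image(np.full(shape, value, dtype=np.uint16), channel, bit_depth)
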