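import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cells_scene():
    from fbdenoise import make_phantom
    return make_phantom(64, 64, "cells", seed=7)
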