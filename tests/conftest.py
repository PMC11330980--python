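import numpy as np
import pytest

from aggretrack import kinetics, synthgen


@pytest.fixture
def wt_params():
    return kinetics.get_preset("WT")


@pytest.fixture
def kr_params():
    return kinetics.get_preset("KR")


@pytest.fixture
def small_geometry():
    cfg = synthgen.GeometryConfig().scaled(0.25)
    cfg.n_neurons = 2
    cfg.n_z = 4
    return synthgen.make_geometry(11, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
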