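import numpy as np
import pytest

from mrsxml import AcquisitionParams, gen_brain_like_sv


@pytest.fixture
def params_1h():
    """1.5 T proton acquisition: 2048 points, ~20 ppm span around 4.7 ppm."""
    return AcquisitionParams(
        transmitter_frequency=63.86, sweep_width=1300.0, num_points=2048,
        reference_ppm=4.7,
    )


@pytest.fixture
def params_small():
    """Small acquisition for fast operator tests."""
    return AcquisitionParams(
        transmitter_frequency=63.86, sweep_width=1300.0, num_points=512,
        reference_ppm=4.7,
    )


@pytest.fixture
def brain_fid(params_1h):
    fid, truth = gen_brain_like_sv(params_1h, seed=7)
    return fid, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
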