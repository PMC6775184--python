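import numpy as np
import pytest

from arrayemg.layout import ArrayLayout, ChannelMask
from arrayemg.simulate import SimConfig


@pytest.fixture(scope="session")
def layout():
    return ArrayLayout.default()


@pytest.fixture(scope="session")
def mask(layout):
    return ChannelMask.default(layout)


@pytest.fixture
def small_cfg():
    """Scaled-down study conditions for fast unit tests."""
    return SimConfig(
        seed=7,
        fs_raw=1024.0,
        motions_per_train_exp=2,
        train_exps_per_finger=1,
        test_exps=1,
        cycles_per_test_exp=5,
        snr_db=10.0,
        crosstalk=0.15,
        artifact_level=0.2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
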