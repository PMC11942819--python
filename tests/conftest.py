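import numpy as np
import pytest

from liftpattern.datasets import paired_vertical_50
from liftpattern.synthetic import CurlSimConfig, simulate_curl


@pytest.fixture(scope="session")
def pairs30():
    """The 30 bundled (vertical deviation, MH) pairs at 50 % load."""
    df = paired_vertical_50()
    return df["deviation_cm"].to_numpy(float), df["mh"].to_numpy(float)


@pytest.fixture()
def noiseless_curl():
    """One noise-free 3-repetition curl trajectory with its ground truth."""
    cfg = CurlSimConfig(jitter_sd_cm=0.0, sway_sd_cm=0.0)
    return simulate_curl(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
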