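import numpy as np
import pytest

from spikeosc import OscillatoryRateParams, generate_train


@pytest.fixture(scope="session")
def osc_train_300s():
    """One 300 s oscillatory train (r0=40, m=0.5, f0=12), reused read-only."""
    params = OscillatoryRateParams(r0=40, m=0.5, f0=12)
    return params, generate_train(params, 300.0, seed=2024)


@pytest.fixture(scope="session")
def homogeneous_train_300s():
    """One 300 s homogeneous Poisson train at 30 sp/s, reused read-only."""
    params = OscillatoryRateParams(r0=30, m=0.0, f0=12)
    return params, generate_train(params, 300.0, seed=2025)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
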