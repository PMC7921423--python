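import numpy as np
import pytest

from condensates import (
    FrapGroundTruth,
    KmcRandom,
    LatticeConfig,
    RateModel,
    initialize,
    make_frap_tracks,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def default_model():
    return RateModel()


@pytest.fixture
def small_state():
    """A sparse 20x20 state: 12 ASK3 units, 8 obstacles."""
    cfg = LatticeConfig(width=20, height=20, n_ask3=12, n_obstacles=8, seed=7)
    return initialize(cfg, KmcRandom(cfg.seed))


@pytest.fixture
def noiseless_frap():
    """Noise-free, quench-free FRAP acquisition and its ground truth."""
    truth = FrapGroundTruth(noise_sd=0.0, quench_rate=0.0)
    table, params = make_frap_tracks(truth, np.random.default_rng(11))
    return truth, table, params
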