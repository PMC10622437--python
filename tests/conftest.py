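import numpy as np
import pytest

from wmaze import align
from wmaze.synthetic import SessionConfig, simulate_session


@pytest.fixture(scope="session")
def planted_session():
    """Small tuned session shared by recovery-style tests."""
    cfg = SessionConfig(n_trials=60, n_units=30, seed=11)
    events, traces, truth = simulate_session(cfg)
    return cfg, events, traces, truth


@pytest.fixture(scope="session")
def planted_tensors(planted_session):
    cfg, events, traces, truth = planted_session
    tensor = align.build_aligned_tensor(events, traces, "zscore")
    deconv = align.build_aligned_tensor(events, truth.deconv, "deconvolved",
                                        targets=tensor.median_durations)
    return tensor, deconv


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
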