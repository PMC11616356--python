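import numpy as np
import pytest

from beadmotility import SimConfig, Trace


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def flat_trace():
    t = np.arange(0, 60.0, 1 / 30.0)
    return Trace(t=t, x=np.zeros_like(t), sample_rate=30.0, meta={"record_id": "flat"})


def make_ramp_trace(slope=0.2, duration=100.0, rate=30.0, noise_sd=0.0, seed=0):
    t = np.arange(0, duration, 1 / rate)
    x = slope * t
    if noise_sd:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, len(t))
    return Trace(t=t, x=x, sample_rate=rate, meta={"record_id": "ramp"})


def quiet_sim_config(**kw):
    """Generator config with all stochastic nuisances switched off."""
    base = dict(noise_sd=0.0, drift_rate_scale=0.0, jump_rate=0.0)
    base.update(kw)
    return SimConfig(**base)
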