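import numpy as np
import pytest

from spikemap.model import ModelParams, SpikeTrain, Trace, simulate_trace
from spikemap.synth import gen_noise, scale_noise_to_level


@pytest.fixture
def ogb_params():
    """Typical organic-dye parameter set."""
    return ModelParams(
        A=0.1, tau=1.0, probe="saturating", gamma=0.1, sigma=0.02, eta=0.0, lam=0.1
    )


@pytest.fixture
def linear_params():
    return ModelParams(A=0.1, tau=1.0, probe="linear", sigma=0.02, eta=0.0, lam=0.1)


def make_noisy_trace(spikes, params, duration, dt, level, kind="white", seed=0):
    """Simulate a trace with band-RMS-calibrated noise; returns (trace, sigma)."""
    clean, _ = simulate_trace(
        spikes, params.with_(sigma=0.0, eta=0.0), duration, dt, seed=seed
    )
    n = int(round(duration / dt))
    eps = gen_noise(kind, n, dt, seed=seed + 1)
    eps = scale_noise_to_level(eps, level, params.A, dt)
    return Trace(values=clean.values + eps, dt=dt), float(np.std(eps))
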