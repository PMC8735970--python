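import numpy as np
import pytest

from selectorswitch.parameters import derive_parameter_set
from selectorswitch.presets import scaled_observables


@pytest.fixture(scope="session")
def scaled_obs():
    """Copy-number/volume scaled observables (one tenth of the measured cell)."""
    return scaled_observables(0.1)


@pytest.fixture(scope="session")
def scaled_unstable(scaled_obs):
    """Scaled unstable switch (fast, equal dissociation everywhere)."""
    return derive_parameter_set(scaled_obs, bO=100.0, bT=100.0, fC=0.0274)


def batch_se(x: np.ndarray, n_batches: int = 20) -> float:
    """Standard error of a correlated time series via batch means."""
    bm = np.array([b.mean() for b in np.array_split(np.asarray(x), n_batches)])
    return float(bm.std(ddof=1) / np.sqrt(n_batches))
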