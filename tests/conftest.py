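import numpy as np
import pytest

from driftscan import ecosim, driftslope


@pytest.fixture(scope="session")
def default_params() -> ecosim.ModelParams:
    return ecosim.ModelParams()


@pytest.fixture(scope="session")
def landmarks(default_params):
    from driftscan import pipeline
    return pipeline.compute_landmarks(default_params)


@pytest.fixture(scope="session")
def fast_mcmc() -> driftslope.MCMCConfig:
    """Small ensemble configuration for unit tests (not for science runs)."""
    return driftslope.MCMCConfig(walkers=16, steps=300, burn=100, thin=2)


def ou_window(theta1: float, sigma: float, n: int, dt: float, seed: int) -> np.ndarray:
    """Euler–Maruyama sample path of dx = theta1 * x dt + sigma dW."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = 0.0
    xi = rng.standard_normal(n - 1) * np.sqrt(dt)
    for i in range(1, n):
        x[i] = x[i - 1] + theta1 * x[i - 1] * dt + sigma * xi[i - 1]
    return x
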