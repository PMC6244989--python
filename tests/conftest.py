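import numpy as np
import pytest

from loopsearch import ModelParams


@pytest.fixture
def loop_params():
    """Reference strongly-returning parameter set (b = 0.2, noiseless)."""
    return ModelParams(
        alpha=10, beta=3, s=0.12, b=0.2, f=0.0, n=3, x0=0.01, y0=0.0, n_steps=5000
    )


@pytest.fixture
def noisy_params(loop_params):
    """Same regime with the strong perturbation switched on."""
    return loop_params.replace(f=0.1, seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
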