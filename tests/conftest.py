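import numpy as np
import pytest

from mriseg import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separable_phantom():
    """Zero-noise, zero-bias 64x64 phantom: exactly 4-valued."""
    return generate_phantom(
        PhantomSpec(width=64, height=64, noise_sigma=0.0, bias_amplitude=0.0, seed=7)
    )


@pytest.fixture
def noisy_phantom():
    return generate_phantom(PhantomSpec(width=48, height=48, noise_sigma=0.08, seed=9))
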