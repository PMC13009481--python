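import numpy as np
import pytest

from slabrestore.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_32():
    """Textured phantom on a 32x32x16 grid (divisible by 2 and 4 in-plane)."""
    return generate_phantom(PhantomSpec(shape=(32, 32, 16), seed=7))


@pytest.fixture(scope="session")
def smooth_phantom():
    """Low-frequency-only phantom: no texture noise, long correlation length."""
    return generate_phantom(
        PhantomSpec(shape=(32, 32, 16), seed=3, texture_scale=6.0, noise_sd=0.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
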