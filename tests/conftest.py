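import numpy as np
import pytest

from focimix import NucleusSpec, generate_nucleus


@pytest.fixture(scope="session")
def default_nucleus():
    """One default-condition synthetic nucleus, shared across tests."""
    return generate_nucleus(NucleusSpec(seed=11))


@pytest.fixture(scope="session")
def clean_nucleus():
    """Noise-free nucleus for tests that need exact rendered intensities."""
    return generate_nucleus(NucleusSpec(seed=11, noise_sd=0.0, impulse_prob=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
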