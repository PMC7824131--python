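import numpy as np
import pytest

from fetalmsp.phantom import PhantomSpec, generate_dataset, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One noiseless 32-cube phantom."""
    return generate_phantom(PhantomSpec(dims=(32, 32, 32), noise_level=0.0, rng_seed=7))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(PhantomSpec(dims=(32, 32, 32), rng_seed=7))


@pytest.fixture(scope="session")
def phantom_cohort():
    """25 noisy 32-cube phantoms shared across tests."""
    return generate_dataset(25, PhantomSpec(dims=(32, 32, 32), rng_seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
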