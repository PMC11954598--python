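import numpy as np
import pytest

from deepvessel import (
    DegradationConfig,
    PhantomConfig,
    background_mask_from_truth,
    generate_vessels,
)


@pytest.fixture(scope="session")
def small_phantom():
    """One seeded clean/truth pair shared by read-only tests."""
    cfg = PhantomConfig(shape=(32, 64, 64))
    clean, truth = generate_vessels(cfg, seed=42)
    return clean, truth


@pytest.fixture(scope="session")
def phantom_background(small_phantom):
    _, truth = small_phantom
    return background_mask_from_truth(truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
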