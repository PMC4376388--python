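import numpy as np
import pytest

from retfractal.phantom import PhantomParams, generate_phantom
from retfractal.vessel import skeletonize


@pytest.fixture(scope="session")
def phantom():
    """One noise-free default phantom shared across tests."""
    return generate_phantom(PhantomParams(), seed=3)


@pytest.fixture(scope="session")
def phantom_skeleton(phantom):
    return skeletonize(phantom.truth_mask)


@pytest.fixture(scope="session")
def small_blob():
    """64x64 irregular blob for brute-force equivalence checks."""
    rng = np.random.default_rng(5)
    img = np.zeros((64, 64), dtype=bool)
    img[20:44, 16:52] = True
    img[rng.integers(0, 64, 200), rng.integers(0, 64, 200)] = True
    img[4:8, 4:8] = False
    return img
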