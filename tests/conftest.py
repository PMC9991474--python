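import numpy as np
import pytest

from osteoseg.phantom import PhantomParams, generate_split

# Small phantoms keep unit tests fast; the full 300x400 geometry is
# exercised where the contract depends on it.
SMALL = dict(height=60, width=80)


@pytest.fixture(scope="session")
def small_cohorts():
    """A fast 8+8 train / 6+6 test phantom split at reduced geometry."""
    p_non = PhantomParams(porosity=0.25, **SMALL)
    p_ost = PhantomParams(porosity=0.45, **SMALL)
    train = generate_split(8, 8, p_non, p_ost, seed=11, id_prefix="train-")
    test = generate_split(6, 6, p_non, p_ost, seed=12, id_prefix="test-")
    return train, test


@pytest.fixture
def rng():
    return np.random.default_rng(0)
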