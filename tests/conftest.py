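import numpy as np
import pytest

from apocvit.synthetic_data import SyntheticSpec, generate_arrays


@pytest.fixture(scope="session")
def small_raw():
    """A small in-memory synthetic dataset shared across tests."""
    spec = SyntheticSpec(n_pairs=12, seed=123)
    return spec, generate_arrays(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
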