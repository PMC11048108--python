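import numpy as np
import pytest

from epiforge.fixtures import load_packaged_mutations, synthetic_protein


@pytest.fixture(scope="session")
def mutations():
    return load_packaged_mutations()


@pytest.fixture(scope="session")
def protein(mutations):
    return synthetic_protein(7, mutations=mutations)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
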