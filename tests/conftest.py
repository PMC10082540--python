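import numpy as np
import pytest

from blockhmm.core_model import GenotypeData, InfluenceStrengths
from blockhmm.hmm_engine import MarkovParameters


@pytest.fixture
def rng():
    return np.random.default_rng(20230407)


@pytest.fixture
def small_data(rng):
    """A 20-subject, 5-site dataset with both phenotypes present."""
    G = rng.integers(0, 3, size=(20, 5))
    y = np.array([0] * 12 + [1] * 8)
    return GenotypeData(G, y)


@pytest.fixture
def theta():
    return InfluenceStrengths(0.4, 0.3, 0.5, 0.6)


def random_markov(rng) -> MarkovParameters:
    pi = rng.dirichlet(np.ones(3))
    A = rng.dirichlet(np.ones(3), size=3)
    return MarkovParameters(pi, A)
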