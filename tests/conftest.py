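import numpy as np
import pytest

import saomhmm as sh


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def study_model():
    return sh.study_model(10)


@pytest.fixture(scope="session")
def study_wave1(study_model):
    return sh.make_initial_network(study_model, np.random.default_rng(314))


def random_network(rng, n=10, density=0.25, directed=True):
    u = (rng.random((n, n)) < density).astype(np.int8)
    np.fill_diagonal(u, 0)
    if not directed:
        upper = np.triu(u, k=1)
        u = upper + upper.T
    return sh.DirectedNetwork(u, directed)
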