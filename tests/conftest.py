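import numpy as np
import pytest

import clonosim as cs


@pytest.fixture(scope="session")
def survey_fixture():
    """Survey-shaped synthetic dataset: 27 individuals × 195 markers."""
    matrix, ancestry, model = cs.survey_dataset(seed=3)
    return matrix, ancestry, model


@pytest.fixture(scope="session")
def four_pop_pure():
    """40 pure individuals (10 per population), 4 populations, 195 markers."""
    model = cs.sample_parental_frequencies(4, 195, divergence=0.25, seed=11)
    ancestry = cs.TrueAncestry.pure([10, 10, 10, 10])
    matrix = cs.simulate_matrix(model, ancestry, seed=11)
    return matrix, ancestry, model


@pytest.fixture(scope="session")
def four_pop_fit(four_pop_pure):
    """Admixture fit at the true K on the pure 4-population data."""
    matrix, _, _ = four_pop_pure
    return cs.fit(matrix, 4, seed=5, n_init=5)
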