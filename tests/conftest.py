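import numpy as np
import pytest

from aamodelkit import poisson_model, random_model, random_tree, simulate_alignment


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230808)


@pytest.fixture(scope="session")
def small_model():
    return random_model(101, concentration=2.0, alpha=0.9)


@pytest.fixture(scope="session")
def poisson():
    return poisson_model()


@pytest.fixture(scope="session")
def six_taxon_case(small_model):
    tree = random_tree(6, 1.8, seed=11)
    aln = simulate_alignment(tree, small_model, 200, seed=12)
    return tree, aln
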