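import random

import pytest

from agios.align import nucleotide_scheme, protein_scheme
from agios.simulate import EvolutionParams, evolve_pair, generate_ancestor


@pytest.fixture(scope="session")
def nuc_scheme():
    return nucleotide_scheme()


@pytest.fixture(scope="session")
def prot_scheme():
    return protein_scheme()


@pytest.fixture(scope="session")
def small_pair():
    """A 30-gene ancestor/derived pair at 5% substitution, no indels."""
    params = EvolutionParams(n_genes=30, sub_rate=0.05, seed=11)
    ancestor = generate_ancestor(params)
    derived, truth = evolve_pair(ancestor, params)
    return ancestor, derived, truth


@pytest.fixture
def rng():
    return random.Random(1234)


def random_nuc(rng, length):
    return "".join(rng.choice("ACGT") for _ in range(length))


def random_prot(rng, length):
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(length))
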