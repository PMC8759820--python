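import numpy as np
import pytest

from strainkit import SimParams, all_pair_conservation, locate_te, simulate_strains
from strainkit.simulate import random_te_library

QUARTET_NEWICK = "((A:0.005,B:0.005):0.003,(C:0.005,D:0.005):0.003);"


@pytest.fixture(scope="session")
def te_library():
    return random_te_library(n_families=2, length=800, seed=11)


@pytest.fixture(scope="session")
def quartet(te_library):
    """Small four-strain simulation shared by locating/conservation tests."""
    params = SimParams(
        tree=QUARTET_NEWICK,
        genome_length=40_000,
        te_library=te_library,
        n_ancestral_te=5,
        te_gain_rate=200.0,
        te_loss_rate=20.0,
        seed=42,
    )
    assemblies, truth = simulate_strains(params)
    return params, assemblies, truth


@pytest.fixture(scope="session")
def quartet_loci(quartet):
    params, assemblies, _ = quartet
    return {s: locate_te(a, params.te_library) for s, a in assemblies.items()}


@pytest.fixture(scope="session")
def quartet_pairs(quartet, quartet_loci):
    _, assemblies, _ = quartet
    return all_pair_conservation(quartet_loci, assemblies)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
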