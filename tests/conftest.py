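import pytest

from ddgpred.embedding import MockBackbone
from ddgpred.fixtures import (
    FixtureSpec,
    make_mutation_tables,
    make_recoverable_dataset,
    make_toy_structures,
)


@pytest.fixture(scope="session")
def mock_backbone():
    return MockBackbone(width=8, seed=11)


@pytest.fixture(scope="session")
def small_pairs(mock_backbone):
    """30 variant pairs with linear-antisymmetric targets."""
    pairs, _ = make_recoverable_dataset(mock_backbone, 30, seed=21)
    return pairs


@pytest.fixture(scope="session")
def mutation_fixture():
    """~200-record heterogeneous mutation fixture with manifest."""
    return make_mutation_tables(FixtureSpec(n_proteins=15, ids_per_protein=7, seed=5))


@pytest.fixture(scope="session")
def toy_structure_files(tmp_path_factory):
    """Toy PDB structures on disk, keyed by name, with expectations."""
    out = tmp_path_factory.mktemp("structures")
    toys = make_toy_structures()
    return {name: (toy.write(out), toy) for name, toy in toys.items()}
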