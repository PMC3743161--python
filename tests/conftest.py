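import numpy as np
import pytest
from rdkit import Chem

from binqsar import synthetic
from binqsar.descriptors import compute_descriptor_matrix


@pytest.fixture(scope="session")
def benchmark_library():
    """162-compound synthetic library with exactly 57 actives at pIC50 7.0."""
    records, y = synthetic.benchmark_dataset(seed=1)
    return records, y


@pytest.fixture(scope="session")
def benchmark_vsa(benchmark_library):
    records, y = benchmark_library
    return compute_descriptor_matrix(records, "vsa_ind"), y


@pytest.fixture(scope="session")
def random_library():
    """500 random generator compounds (for per-molecule invariant sweeps)."""
    cfg = synthetic.LibrarySimConfig(n_compounds=500, seed=11)
    return synthetic.generate_compound_library(cfg)


def mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    assert m is not None, smiles
    return m


@pytest.fixture
def rng():
    return np.random.default_rng(0)
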