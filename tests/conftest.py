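import numpy as np
import pytest

from molcycle.mol_features import parse_molecule
from molcycle.pipeline import make_toy_molecules


@pytest.fixture(scope="session")
def toy_molecules():
    return make_toy_molecules()


@pytest.fixture(scope="session")
def toy_valid(toy_molecules):
    return [m for m in toy_molecules if m.valid]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_library():
    smiles = ["CCO", "CCCO", "CCN", "c1ccccc1", "Cc1ccccc1", "C1CCCCC1",
              "OCCO", "CC(C)O", "c1ccncc1", "CC(C)C"]
    return [parse_molecule(s) for s in smiles]
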