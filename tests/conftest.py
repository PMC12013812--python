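from pathlib import Path

import pytest

from molanneal.cli_io import generate_fixtures
from molanneal.molgraph import parse_molecule, read_smiles_file

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def druglike_corpus():
    mols = read_smiles_file(DATA / "druglike.smi")
    assert len(mols) >= 100
    return mols


@pytest.fixture(scope="session")
def bundle():
    return generate_fixtures(seed=0)


@pytest.fixture(scope="session")
def named(bundle):
    return bundle.named


@pytest.fixture()
def methane():
    return parse_molecule("C")


@pytest.fixture()
def ethanol():
    return parse_molecule("CCO")


@pytest.fixture()
def pentane():
    return parse_molecule("CCCCC")
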