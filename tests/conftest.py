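import numpy as np
import pytest

from evochem import (MoleculeRecord, default_seed_library,
                     load_reaction_library)
from evochem.fixtures import default_complementary_candidates
from evochem.reactions import build_complementary_library


@pytest.fixture(scope="session")
def all_rxn():
    return load_reaction_library(None, "AllRxn")


@pytest.fixture(scope="session")
def comp_library(all_rxn):
    return build_complementary_library(default_complementary_candidates(), all_rxn)


@pytest.fixture(scope="session")
def seed_smiles():
    return default_seed_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_scored(values, key="primary"):
    """Records named r1..rn carrying the given scores (ethanol homologs so
    canonical SMILES are distinct for tie-breaking)."""
    recs = []
    for i, v in enumerate(values):
        recs.append(MoleculeRecord(
            id=f"r{i + 1}", smiles="C" * (i + 1) + "O",
            scores={key: float(v)},
        ))
    return recs


@pytest.fixture()
def scored_factory():
    return make_scored
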