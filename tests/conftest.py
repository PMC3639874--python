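import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from oascreen.chemgraph import molecule_from_smiles
from oascreen.fixtures import FixtureSpec, generate_planted_dataset


@pytest.fixture(scope="session")
def mols():
    """Small named molecules used across test modules."""
    smiles = {
        "ethanol": "CCO",
        "propane": "CCC",
        "benzene": "c1ccccc1",
        "butane": "CCCC",
        "methane": "C",
        "ammonia": "N",
        "pyridine": "c1ccncc1",
        "toluene": "Cc1ccccc1",
        "phenol": "Oc1ccccc1",
        "acetone": "CC(=O)C",
    }
    return {name: molecule_from_smiles(s, name) for name, s in smiles.items()}


@pytest.fixture(scope="session")
def small_fixture():
    """A small planted-pharmacophore dataset (fast to screen)."""
    spec = FixtureSpec(n_actives=10, n_decoys=30, n_clusters=3, seed=7)
    dataset, query = generate_planted_dataset(spec)
    return spec, dataset, query


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
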