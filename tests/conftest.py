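import numpy as np
import pytest

from subretro.chem import canonicalize
from subretro.synthetic import (
    GeneratorConfig,
    generate_core_library,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_reactions=120, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """A 120-reaction corpus shared across tests (deterministic, seed 11)."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def cores(small_config):
    return generate_core_library(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sample_molecules():
    """A mixed bag of hand-picked molecules used across modules."""
    smiles = [
        "CCO",
        "c1ccccc1",
        "CC(=O)OCCc1ccccc1",
        "CC#CCO",
        "COc1cc(CCCBr)ccn1",
        "C/C=C/C(=O)O",
        "CC(N)C(=O)O",
        "Clc1ccc2ccccc2c1",
        "CN(C)CCOC(=O)c1ccco1",
        "O=[N+]([O-])c1ccccc1",
    ]
    return [canonicalize(s) for s in smiles]
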