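"""Shared fixtures: small molecule sets and synthetic data, all generated in-process."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from tpascreen.dataset_io import MeasurementRecord


@pytest.fixture(scope="session")
def mol():
    def _mol(smiles: str) -> Chem.Mol:
        m = Chem.MolFromSmiles(smiles)
        assert m is not None, f"fixture SMILES failed to parse: {smiles}"
        return m

    return _mol


#: 30-molecule fixture with hand-derivable conjugation diameters
#: (independent all-pairs BFS oracle recomputes these in the tests).
CONJUGATION_FIXTURE = [
    "C=CC=C",                # butadiene
    "c1ccccc1",              # benzene
    "c1ccc(/C=C/c2ccccc2)cc1",  # stilbene
    "C=C", "CC", "CCO",
    "C=CC=CC=C", "C=CC=CC=CC=C", "C=CC=CC=CC=CC=C",
    "c1ccc2ccccc2c1",        # naphthalene
    "c1ccc(-c2ccccc2)cc1",   # biphenyl
    "Cc1ccccc1",             # toluene
    "Nc1ccc(cc1)[N+](=O)[O-]",  # 4-nitroaniline
    "N(c1ccccc1)(c1ccccc1)c1ccccc1",  # triphenylamine
    "C=Cc1ccccc1",           # styrene
    "O=Cc1ccccc1",           # benzaldehyde
    "N#Cc1ccccc1",           # benzonitrile
    "CN(C)c1ccc(C=O)cc1",    # DMABA
    "c1ccncc1",              # pyridine
    "c1ccsc1",               # thiophene
    "c1ccoc1",               # furan
    "C1=CC=CC1",             # cyclopentadiene
    "C1CCCCC1",              # cyclohexane
    "CC(=O)C",               # acetone
    "C#CC#C",                # diacetylene
    "c1ccc(/C=C/c2ccc(/C=C/c3ccccc3)cc2)cc1",  # distyrylbenzene
    "CN(C)C=CC=C[N+](=O)[O-]",
    "Oc1ccccc1",             # phenol
    "CSc1ccccc1",            # thioanisole
    "O=S(=O)(c1ccccc1)c1ccccc1",  # diphenyl sulfone
]


@pytest.fixture(scope="session")
def conjugation_fixture_mols(mol):
    return [(smi, mol(smi)) for smi in CONJUGATION_FIXTURE]


@pytest.fixture
def toy_records():
    return [
        MeasurementRecord("c1ccccc1C=O", 12.0, 550.0, "toluene"),
        MeasurementRecord("c1ccc(/C=C/c2ccccc2)cc1", 50.0, 800.0, "toluene"),
        MeasurementRecord("Nc1ccc(cc1)[N+](=O)[O-]", 80.0, 1200.0, "dmso"),
        MeasurementRecord("C[Si](C)(C)c1ccccc1", 30.0, 800.0, "toluene"),
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
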