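import numpy as np
import pytest

from vsfunnel.mol_model import Conformer, Molecule, parse_smiles
from vsfunnel.synthetic_data import GeneratorConfig, gen_library, gen_pocket


@pytest.fixture(scope="session")
def pocket():
    return gen_pocket()


@pytest.fixture(scope="session")
def small_library():
    """Eight drug-like compounds, 1-3 conformers each, fixed seed."""
    confs, truth = gen_library(GeneratorConfig(seed=42, n_compounds=8, conformers=(1, 3)))
    return confs, truth


def toy_conformer(elements, coords, cid="toy", conf_id="0"):
    """Bond-free conformer for shape-engine tests (shape needs atoms only)."""
    mol = Molecule(id=cid, atoms=[(el, 0, False, 0) for el in elements], bonds=[])
    return Conformer(molecule=mol, coords=np.asarray(coords, dtype=float), conformer_id=conf_id)


@pytest.fixture
def asymmetric_toys():
    """A deliberately asymmetric 5-atom pair for overlay-optimizer tests."""
    a = toy_conformer(
        ["C", "C", "N", "O", "C"],
        [[0, 0, 0], [1.5, 0, 0], [2.4, 1.1, 0.3], [0.2, -1.3, 0.9], [-1.2, 0.7, -0.6]],
        cid="toyA",
    )
    b = toy_conformer(
        ["C", "C", "N", "O", "C"],
        [[0.3, 0.1, 0], [1.7, -0.2, 0.2], [2.2, 1.2, 0.6], [-0.4, -1.2, 0.7], [-1.4, 0.9, -0.2]],
        cid="toyB",
    )
    return a, b
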