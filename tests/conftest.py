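import numpy as np
import pytest

from rgbchem.chem_tables import load_element_table, load_pair_params
from rgbchem.xyz_io import Molecule


@pytest.fixture(scope="session")
def elements():
    return load_element_table()


@pytest.fixture(scope="session")
def pair_params():
    return load_pair_params()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def h2():
    return Molecule("h2", ("H", "H"), [[0, 0, 0], [0, 0, 0.74]])


@pytest.fixture
def water():
    return Molecule(
        "water", ("O", "H", "H"),
        [[0.0, 0.0, 0.0], [0.9584, 0.0, 0.0], [-0.2392, 0.9281, 0.0]],
        label=7.6,
    )


@pytest.fixture
def methane():
    d = 1.09 / np.sqrt(3)
    return Molecule(
        "ch4", ("C", "H", "H", "H", "H"),
        [[0, 0, 0], [d, d, d], [-d, -d, d], [-d, d, -d], [d, -d, -d]],
    )


def _random_molecule(rng, n_heavy=None, mol_id="rand"):
    """Random CHONF molecule with well-separated atoms (geometry only)."""
    heavy = ["C", "N", "O", "F"]
    n_heavy = n_heavy or int(rng.integers(1, 10))
    n_h = int(rng.integers(0, 2 * n_heavy + 1))
    symbols = [str(rng.choice(heavy)) for _ in range(n_heavy)] + ["H"] * n_h
    coords = []
    while len(coords) < len(symbols):
        p = rng.uniform(-4, 4, size=3)
        if all(np.linalg.norm(p - c) > 0.7 for c in coords):
            coords.append(p)
    return Molecule(mol_id, tuple(symbols), np.array(coords), label=float(rng.normal(5, 1)))


@pytest.fixture
def random_molecule_factory():
    return _random_molecule
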