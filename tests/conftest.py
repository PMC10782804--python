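import numpy as np
import pytest

from dockgraph.structure_io import Atom, Complex, Residue
from dockgraph.synthetic_data import make_benchmark


def make_residue(chain_id, number, name, atom_positions, atom_names=None,
                 elements=None, icode=""):
    """Residue from raw coordinates; defaults to carbon pseudo-atoms."""
    atom_positions = np.atleast_2d(np.asarray(atom_positions, float))
    n = len(atom_positions)
    atom_names = atom_names or [f"C{i}" if i else "CA" for i in range(n)]
    elements = elements or ["C"] * n
    atoms = [Atom(an, el, pos) for an, el, pos in zip(atom_names, elements, atom_positions)]
    return Residue(chain_id, number, icode, name, atoms)


def two_residue_complex(separation, name_a="GLY", name_b="ALA"):
    """Two single-residue chains whose single atoms sit ``separation`` Å apart."""
    res_a = make_residue("A", 1, name_a, [[0.0, 0.0, 0.0]])
    res_b = make_residue("B", 1, name_b, [[separation, 0.0, 0.0]])
    return Complex("toy", {"A": [res_a], "B": [res_b]})


@pytest.fixture(scope="session")
def small_benchmark():
    """4 complexes x 6 decoys at embedding width 8; shared across tests."""
    return make_benchmark(4, 6, embedding_dim=8, seed=11, n_res_per_chain=20)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
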