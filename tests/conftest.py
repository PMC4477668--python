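import numpy as np
import pytest

from rbscore.pipeline import featurize_chain
from rbscore.structure import Atom, Complex, Residue
from rbscore.synthetic import FixtureSpec, make_toy_complex

TEST_DENSITY = 480  # dots/atom for geometry-heavy tests; default 960 where asserted


def make_residue(chain_id, idx, res_type, atom_specs, author=None):
    """atom_specs: list of (name, element, (x, y, z))."""
    atoms = [Atom(n, e, np.array(c, dtype=float)) for n, e, c in atom_specs]
    return Residue(chain_id=chain_id, seq_index=idx, res_type=res_type,
                   atoms=atoms, author_number=author if author is not None else idx + 1)


def single_atom_residue(chain_id, idx, res_type, coord, name="CA", element="C"):
    return make_residue(chain_id, idx, res_type, [(name, element, coord)])


@pytest.fixture(scope="session")
def toy_fixture():
    """One deterministic planted-interface complex shared across tests."""
    spec = FixtureSpec(n_residues=30, interface_size=6, seed=5)
    cx, interface = make_toy_complex(spec)
    return cx, interface, spec


@pytest.fixture(scope="session")
def toy_featurized(toy_fixture):
    cx, interface, _ = toy_fixture
    table, graph = featurize_chain(cx, "A", density=TEST_DENSITY)
    return cx, interface, table, graph


@pytest.fixture()
def tiny_complex():
    """3-residue peptide 40 A away from a 2-nt RNA, built in memory."""
    protein = [
        make_residue("A", 0, "ALA", [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
                                     ("C", "C", (2.3, 1.2, 0))]),
        make_residue("A", 1, "GLY", [("N", "N", (3.8, 0, 0)), ("CA", "C", (5.3, 0, 0)),
                                     ("C", "C", (6.1, 1.2, 0))]),
        make_residue("A", 2, "ARG", [("N", "N", (7.6, 0, 0)), ("CA", "C", (9.1, 0, 0)),
                                     ("C", "C", (9.9, 1.2, 0))]),
    ]
    na = [
        make_residue("B", 0, "U", [("P", "P", (40, 0, 0)), ("C1'", "C", (41, 0, 0))]),
        make_residue("B", 1, "G", [("P", "P", (43, 0, 0)), ("C1'", "C", (44, 0, 0))]),
    ]
    return Complex(protein_chains={"A": protein}, na_chains={"B": na},
                   chain_kinds={"A": "protein", "B": "RNA"})
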