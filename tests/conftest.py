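import numpy as np
import pytest

from capsipy import fixtures
from capsipy.structure_io import Atom, Chain, Residue, Structure


@pytest.fixture(scope="session")
def random_structure():
    """Dense random scatter of idealized side chains (seeded)."""
    return fixtures.make_random_structure(n_residues=200, box_size=35.0, seed=11)


@pytest.fixture(scope="session")
def vertex_capsid():
    return fixtures.make_vertex_capsid(radius=20.0)


@pytest.fixture
def single_atom_chain():
    def _make(chain_id="X", element="C", xyz=(0.0, 0.0, 0.0), res_name="ALA",
              atom_name="CB", role="unassigned"):
        res = Residue(chain_id, 1, res_name,
                      [Atom(1, atom_name, element, np.array(xyz, dtype=float))])
        return Chain(chain_id, [res], protomer_role=role)
    return _make


@pytest.fixture
def minimal_pdb(tmp_path):
    """Hand-written 1-chain, 1-residue, 3-atom PDB record."""
    text = (
        "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00 10.00           N\n"
        "ATOM      2  CA  ALA A   1       2.000   2.500   3.000  1.00 10.00           C\n"
        "ATOM      3  CB  ALA A   1       3.000   2.000   4.000  1.00 10.00           C\n"
        "END\n"
    )
    path = tmp_path / "minimal.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """One atom with two alternate locations A (occ 0.4) and B (occ 0.6)."""
    text = (
        "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.40 10.00           C\n"
        "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.60 10.00           C\n"
        "END\n"
    )
    path = tmp_path / "altloc.pdb"
    path.write_text(text)
    return path


def make_ring_structure(cation_xyz, ring_type="TYR", cation_type="ARG"):
    """Ring in the z=0 plane centered at the origin + cation at given xyz.

    A lower-level variant of the planted-pair generator for tests that
    place the cation at an arbitrary point rather than (distance, theta).
    """
    xyz = np.asarray(cation_xyz, dtype=float)
    d = float(np.linalg.norm(xyz))
    theta = float(np.degrees(np.arccos(np.clip(abs(xyz[2]) / d, -1, 1))))
    s = fixtures.make_planted_pair(
        fixtures.PlantedPairSpec(distance=d, theta=theta,
                                 cation_type=cation_type, ring_type=ring_type)
    )
    return s
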