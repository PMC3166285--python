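import numpy as np
import pytest

from ringscan.io_model import Alignment, Atom, Chain, Residue, Structure


@pytest.fixture
def two_residue_pdb(tmp_path):
    """A minimal hand-written two-residue PDB file."""
    text = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
TER       7      GLY A   2
END
"""
    path = tmp_path / "mini.pdb"
    path.write_text(text)
    return path


def make_structure(coords, struct_id="s", chain_id="A", atom_name="CA",
                   res_name="ALA"):
    """Structure with one atom per residue at the given coordinates."""
    residues = [
        Residue(chain_id, k, res_name,
                [Atom(atom_name, "C", tuple(map(float, c)))])
        for k, c in enumerate(np.asarray(coords, dtype=float), start=1)
    ]
    return Structure(id=struct_id, chains=[Chain(id=chain_id, residues=residues)])


def trivial_alignment(ids, length, letter="A"):
    return Alignment(row_ids=list(ids), rows=[letter * length] * len(ids))


def random_rotation(rng):
    """A uniform random proper rotation matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
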