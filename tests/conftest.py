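import numpy as np
import pytest

from foldswitch_bench.structio import Atom, RegionSpec, Residue, Structure
from foldswitch_bench.synthetic import build_helix, make_pair

# hand-written 3-residue PDB (ALA-GLY-SER) with full backbone + some sidechain
THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 50.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 50.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 50.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 50.00           O
ATOM      5  CB  ALA A   1       2.000  -0.750  -1.200  1.00 50.00           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00 60.00           N
ATOM      7  CA  GLY A   2       3.988   2.835   0.000  1.00 60.00           C
ATOM      8  C   GLY A   2       5.500   2.700   0.000  1.00 60.00           C
ATOM      9  O   GLY A   2       6.100   1.630   0.000  1.00 60.00           O
ATOM     10  N   SER A   3       6.150   3.850   0.000  1.00 70.00           N
ATOM     11  CA  SER A   3       7.600   3.900   0.000  1.00 70.00           C
ATOM     12  C   SER A   3       8.200   5.300   0.000  1.00 70.00           C
ATOM     13  O   SER A   3       7.500   6.310   0.000  1.00 70.00           O
ATOM     14  OG  SER A   3       8.150   3.150   1.150  1.00 70.00           O
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.60 10.00           C
ATOM      3  CA BALA A   1       1.500   0.100   0.000  0.40 10.00           C
ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      5  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00 10.00           N
ATOM      7  CA  GLY A   2       3.988   2.835   0.000  1.00 10.00           C
ATOM      8  C   GLY A   2       5.500   2.700   0.000  1.00 10.00           C
ATOM      9  N   SER A   3       6.150   3.850   0.000  1.00 10.00           N
ATOM     10  CA  SER A   3       7.600   3.900   0.000  1.00 10.00           C
ATOM     11  C   SER A   3       8.200   5.300   0.000  1.00 10.00           C
TER
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_RESIDUE_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture(scope="session")
def helix20():
    return build_helix("ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture(scope="session")
def default_pair():
    """60-residue synthetic fold-switch pair, 30-residue region (16-45)."""
    seq = "ACDEFGHIKLMNPQRSTVWY" * 3
    return make_pair(seq, RegionSpec(16, 45), seed=1)


def make_structure(coords_by_residue, names=None, bfactor=0.0):
    """Small helper: build a Structure from {resnum: {atom: xyz}}."""
    residues = []
    for num in sorted(coords_by_residue):
        atom_map = coords_by_residue[num]
        resname = (names or {}).get(num, "ALA")
        atoms = tuple(
            Atom(a, a[0], tuple(np.asarray(xyz, dtype=float)), bfactor)
            for a, xyz in atom_map.items()
        )
        residues.append(Residue(name=resname, number=num, atoms=atoms))
    return Structure(id="toy", chain="A", residues=tuple(residues))
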