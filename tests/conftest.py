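"""Shared fixtures: hand-written PDB snippets and synthetic structures."""

from __future__ import annotations

import numpy as np
import pytest

from pocketseer.synthetic import SyntheticSpec, build_backbone, plant_cavity

# A minimal 3-residue chain, one MSE (selenomethionine) chain, and a
# hetero (ATP-like) group, in strict PDB column layout.
THREE_RESIDUE_PDB = """\
REMARK   2 RESOLUTION.    1.80 ANGSTROMS.
REMARK 350 BIOMOLECULE: 1
REMARK 350 AUTHOR DETERMINED BIOLOGICAL UNIT: MONOMERIC
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.321   7.395  -4.804  1.00 10.00           C
ATOM      4  O   ALA A   1      12.270   8.343  -5.585  1.00 10.00           O
ATOM      5  N   GLY A   2      12.953   7.424  -3.635  1.00 11.00           N
ATOM      6  CA  GLY A   2      13.680   8.615  -3.218  1.00 11.00           C
ATOM      7  C   GLY A   2      14.825   8.254  -2.285  1.00 11.00           C
ATOM      8  O   GLY A   2      14.834   7.169  -1.700  1.00 11.00           O
ATOM      9  N   SER A   3      15.788   9.158  -2.142  1.00 12.00           N
ATOM     10  CA  SER A   3      16.944   8.948  -1.280  1.00 12.00           C
ATOM     11  C   SER A   3      17.805  10.199  -1.189  1.00 12.00           C
ATOM     12  O   SER A   3      17.549  11.189  -1.875  1.00 12.00           O
END
"""

MSE_PDB = """\
REMARK   2 RESOLUTION.    2.00 ANGSTROMS.
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
HETATM    4  N   MSE A   2       1.330   2.440   0.500  1.00  0.00           N
HETATM    5  CA  MSE A   2       1.850   3.800   0.600  1.00  0.00           C
HETATM    6  C   MSE A   2       3.200   3.900   1.300  1.00  0.00           C
HETATM    7 SE   MSE A   2       0.600   4.900   1.700  1.00  0.00          SE
ATOM      8  N   GLY A   3       3.900   5.000   1.100  1.00  0.00           N
ATOM      9  CA  GLY A   3       5.250   5.250   1.650  1.00  0.00           C
ATOM     10  C   GLY A   3       6.200   6.100   0.800  1.00  0.00           C
END
"""

LIGAND_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       1.330   2.440   0.500  1.00  0.00           N
ATOM      5  CA  GLY A   2       1.850   3.800   0.600  1.00  0.00           C
ATOM      6  C   GLY A   2       3.200   3.900   1.300  1.00  0.00           C
HETATM    7  PG  ATP A 101       8.000   8.000   8.000  1.00  0.00           P
HETATM    8  O1G ATP A 101       8.800   8.900   8.500  1.00  0.00           O
HETATM    9  O2G ATP A 101       7.100   8.600   7.200  1.00  0.00           O
HETATM   10  O   HOH A 201      12.000  12.000  12.000  1.00  0.00           O
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_RESIDUE_PDB)
    return p


@pytest.fixture
def mse_pdb(tmp_path):
    p = tmp_path / "mse.pdb"
    p.write_text(MSE_PDB)
    return p


@pytest.fixture
def ligand_pdb(tmp_path):
    p = tmp_path / "ligand.pdb"
    p.write_text(LIGAND_PDB)
    return p


@pytest.fixture(scope="session")
def helix20():
    return build_backbone(SyntheticSpec(n_residues=20, fold="helix", seed=1))


@pytest.fixture(scope="session")
def cavity_structure():
    """Small chain with a planted 3.5 A spherical cavity well off the chain."""
    st = build_backbone(SyntheticSpec(n_residues=5, fold="helix", seed=2))
    center = st.heavy_coords().mean(axis=0) + np.array([15.0, 0.0, 0.0])
    return plant_cavity(st, center, 3.5), center, 3.5


def random_rotation(seed: int) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=seed).as_matrix()
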