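import numpy as np
import pytest

from kinodyn.structure import Structure
from kinodyn.synthetic import make_two_lobe, make_two_state_chain


THREE_RESIDUE_PDB = """\
TITLE     three residue fixture
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.753   7.100  -4.974  1.00  0.00           C
ATOM      4  CA  GLY A   2      14.856   7.950  -4.128  1.00  0.00           C
ATOM      5  C   GLY A   2      15.550   7.320  -2.925  1.00  0.00           C
ATOM      6  N   SER A   3      16.100   6.120  -3.005  1.00  0.00           N
ATOM      7  CA  SER A   3      17.200   5.403  -2.354  1.00  0.00           C
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture(scope="session")
def two_lobe():
    return make_two_lobe(seed=2024)


@pytest.fixture(scope="session")
def two_lobe_clamped():
    return make_two_lobe(seed=2024, clamp=True)


@pytest.fixture(scope="session")
def two_state():
    return make_two_state_chain(seed=11)


@pytest.fixture(scope="session")
def paired_studies():
    """Free vs clamped open↔closed free-energy studies over three seeds.

    The slowest computation of the suite; shared between the directional
    free-energy tests.
    """
    from kinodyn.pipeline import paired_two_state_study

    return {seed: paired_two_state_study(seed=seed)
            for seed in (1, 2, 3)}


@pytest.fixture(scope="session")
def two_state_clamped():
    return make_two_state_chain(seed=11, clamp=True)


def bead_structure(xyz, chain="A") -> Structure:
    """Minimal Cα Structure around a coordinate array."""
    xyz = np.asarray(xyz, dtype=float)
    n = len(xyz)
    return Structure(
        atom_names=np.array(["CA"] * n),
        elements=np.array(["C"] * n),
        res_numbers=np.arange(1, n + 1),
        icodes=np.array([""] * n),
        res_names=np.array(["ALA"] * n),
        chain_ids=np.array([chain] * n),
        coords=xyz[None],
    )
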