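import numpy as np
import pytest

from oligoflex import synthetic as syn


@pytest.fixture(scope="session")
def helix_chain():
    """One 20-residue toy chain with a mixed composition."""
    return syn.make_toy_structure(
        syn.GeneratorSpec(seed=11, n_chains=1, chain_length=20)
    )


@pytest.fixture(scope="session")
def tetramer():
    """A 4-chain (A-D) toy tetramer on the dimer-of-dimers grid."""
    return syn.make_tetramer(seed=7, chain_length=12)


@pytest.fixture(scope="session")
def dimer_with_contacts():
    """Two facing chains with 3 designed ion pairs and 2 designed H-bonds."""
    return syn.make_interface_dimer(n_ip=3, n_hb=2, seed=5)


@pytest.fixture(scope="session")
def ou_trajectory(helix_chain):
    """Stationary OU dynamics: sigma=0.5 Å (3D RMSF), tau_c=10 ps, dt=1 ps."""
    return syn.make_ou_trajectory(
        helix_chain, sigma=0.5, tau_c=10.0, n_frames=20000, dt=1.0, seed=23
    )


class AB_PAIR:
    """Minimal two-chain interface stand-in for dimer-level tests."""

    label = "ab"
    pairs = (("A", "B"), ("A", "B"))

    def spans(self, a, b):
        return {a, b} == {"A", "B"}


@pytest.fixture()
def ab_interface():
    return AB_PAIR()


MINIMAL_PDB = """\
CRYST1   30.000   30.000   30.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.000   2.500   3.500  1.00  0.00           C
ATOM      3  C   ALA A   1       3.200   2.100   3.100  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       1.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA BSER A   1       9.000   0.000   0.000  0.60  0.00           C
ATOM      4  C   SER A   1       2.200   0.500   0.200  1.00  0.00           C
END
"""


@pytest.fixture()
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture()
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p
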