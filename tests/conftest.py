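import numpy as np
import pytest

from gapstat import make_gjc_like_channel


@pytest.fixture(scope="session")
def gjc_channel():
    """Docked two-hemichannel toy with twelve chelated Ca sites."""
    return make_gjc_like_channel()


@pytest.fixture(scope="session")
def gjc_channel_free():
    """Same architecture without bound metals."""
    return make_gjc_like_channel(include_metals=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


THREE_ATOM_PDB = """\
CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   GLY A  10      11.000  12.000  13.000  1.00 20.00           N
ATOM      2  CA  GLY A  10      12.300  12.600  13.200  1.00 21.00           C
HETATM    3 CA    CA A 101      15.500  16.500  17.500  0.50 30.00          CA
END
"""


@pytest.fixture()
def three_atom_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_ATOM_PDB)
    return p
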