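import numpy as np
import pytest

from dnahotspot.structure import read_pdb
from dnahotspot.synthetic import ToyComplexSpec, make_toy_complex


def pdb_line(serial, name, resname, chain, resnum, x, y, z, element=None, altloc=" ", occ=1.0, record="ATOM"):
    element = element or name[0]
    name_field = name if len(name) == 4 else f" {name}"
    return (
        f"{record:<6s}{serial:>5d} {name_field:<4s}{altloc:1s}{resname:>3s} "
        f"{chain:1s}{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture(scope="session")
def toy_pdb_text():
    return make_toy_complex(ToyComplexSpec(peptide_length=6, dna_length=8, gap=3.5, seed=1))


@pytest.fixture(scope="session")
def toy_model(toy_pdb_text):
    return read_pdb(toy_pdb_text)


@pytest.fixture(scope="session")
def far_pdb_text():
    return make_toy_complex(ToyComplexSpec(peptide_length=6, dna_length=8, gap=30.0, seed=1))


@pytest.fixture(scope="session")
def far_model(far_pdb_text):
    return read_pdb(far_pdb_text)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
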