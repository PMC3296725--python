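import numpy as np
import pytest

import hxfold as hx
from hxfold.fixtures import (build_ideal_hairpin, build_ideal_helix,
                             build_two_island)


@pytest.fixture(scope="session")
def helix12():
    return hx.parse_pdb(build_ideal_helix(12), "helix12")


@pytest.fixture(scope="session")
def hairpin():
    return hx.parse_pdb(build_ideal_hairpin(6), "hairpin")


@pytest.fixture(scope="session")
def two_island_far():
    pdb, table, truth = build_two_island(20.0, 8, seed=3)
    return hx.parse_pdb(pdb, "islands"), table, truth


@pytest.fixture(scope="session")
def rate_table():
    return hx.ReferenceRateTable.load()


@pytest.fixture(scope="session")
def kpro_table():
    return hx.ProlineIsomerTable.load()


def synthetic_structure(coords_by_residue, names=None, chain="A"):
    """Build a ProteinStructure from {resnum: {atom: xyz}} dicts."""
    names = names or {}
    residues = [
        hx.Residue(chain, num, " ", names.get(num, "ALA"),
                   {a: np.asarray(xyz, float) for a, xyz in atoms.items()})
        for num, atoms in sorted(coords_by_residue.items())
    ]
    return hx.ProteinStructure("synthetic", residues)
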