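import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from csmpred.structure import (
    PharmacophoreTable,
    assign_pharmacophores,
    read_pdb,
)
from csmpred.synthetic import FixtureSpec, generate_structure


@pytest.fixture(scope="session")
def table():
    return PharmacophoreTable.default()


@pytest.fixture(scope="session")
def cloud_structure(tmp_path_factory, table):
    """A 20-residue random cloud, parsed and labelled through the package."""
    path = tmp_path_factory.mktemp("pdb") / "cloud.pdb"
    path.write_text(generate_structure(FixtureSpec(kind="point-cloud", n_residues=20, seed=1)))
    return assign_pharmacophores(read_pdb(path), table)


@pytest.fixture(scope="session")
def helix_structure(tmp_path_factory, table):
    path = tmp_path_factory.mktemp("pdb") / "helix.pdb"
    path.write_text(generate_structure(FixtureSpec(kind="ideal-helix", n_residues=15, seed=0)))
    return assign_pharmacophores(read_pdb(path), table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_gly_pdb_lines(altloc: bool = False, water: bool = False):
    lines = []
    if altloc:
        lines += [
            "ATOM      1  N  AGLY A   1       0.000   0.800   0.000  0.60  0.00           N",
            "ATOM      2  N  BGLY A   1       0.100   0.900   0.100  0.40  0.00           N",
        ]
    else:
        lines.append(
            "ATOM      1  N   GLY A   1       0.000   0.800   0.000  1.00  0.00           N"
        )
    lines += [
        "ATOM      3  CA  GLY A   1       1.200   0.000   0.000  1.00  0.00           C",
        "ATOM      4  C   GLY A   1       2.100  -1.000   0.500  1.00  0.00           C",
        "ATOM      5  O   GLY A   1       3.100  -1.500   0.000  1.00  0.00           O",
    ]
    if water:
        lines.append(
            "HETATM    6  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O"
        )
    lines.append("END")
    return lines
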