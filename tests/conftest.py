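from __future__ import annotations

import numpy as np
import pytest

from locohd.core import ComparisonSettings, Environment
from locohd.fixtures import make_structure, worked_example_cloud

ALL20 = "ACDEFGHIKLMNPQRSTVWY"

TOY_PDB = """\
ATOM      1  N   ALA A   1      -1.200   0.850   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.250   0.700   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.400   1.920   0.250  1.00  0.00           O
ATOM      5  CB  ALA A   1       0.000  -0.800   1.250  1.00  0.00           C
ATOM      6  H   ALA A   1      -1.900   0.300   0.400  1.00  0.00           H
ATOM      7  N   SER A   2       2.600   0.850   0.000  1.00  0.00           N
ATOM      8  CA ASER A   2       3.800   0.000   0.000  0.60  0.00           C
ATOM      9  CA BSER A   2       3.850   0.050   0.050  0.40  0.00           C
ATOM     10  C   SER A   2       5.050   0.700   0.000  1.00  0.00           C
ATOM     11  O   SER A   2       5.200   1.920   0.250  1.00  0.00           O
ATOM     12  CB  SER A   2       3.800  -0.800   1.250  1.00  0.00           C
ATOM     13  OG  SER A   2       3.800  -1.500   2.400  1.00  0.00           O
ATOM     14  N   GLY A   3       6.400   0.850   0.000  1.00  0.00           N
ATOM     15  CA  GLY A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM     16  C   GLY A   3       8.850   0.700   0.000  1.00  0.00           C
ATOM     17  O   GLY A   3       9.000   1.920   0.250  1.00  0.00           O
HETATM   18 SE   MSE A   4      11.400  -1.500   2.400  1.00  0.00          SE
HETATM   19  O   HOH A 101      15.000   5.000   5.000  1.00  0.00           O
TER
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def worked_cloud():
    return worked_example_cloud()


@pytest.fixture
def all20_structure():
    return make_structure(ALL20)


@pytest.fixture
def toy_settings():
    return ComparisonSettings(scheme_name="toy", hetero_only=False, truncation_radius=1e9)


def random_environment(
    rng: np.random.Generator,
    type_set: tuple[str, ...] = ("A", "B", "C"),
    max_neighbors: int = 15,
    max_radius: float = 12.0,
) -> Environment:
    """A syntactically valid random environment (anchor at 0 Å included)."""
    n = int(rng.integers(0, max_neighbors + 1))
    dists = np.sort(rng.uniform(0.1, max_radius, size=n))
    types = rng.choice(type_set, size=n)
    anchor_type = str(rng.choice(type_set))
    neighbors = [(0.0, anchor_type)] + [(float(d), str(t)) for d, t in zip(dists, types)]
    return Environment(anchor_ptype=anchor_type, neighbors=neighbors, type_set=type_set)
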