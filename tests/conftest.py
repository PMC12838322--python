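import numpy as np
import pytest
from hypothesis import settings

from stabscan.structure import Structure, parse_pdb

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")
from stabscan.synth import ResidueSpec, build_backbone, build_peptide

GLY_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  1.00           N
ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00  1.00           C
ATOM      3  C   GLY A   1      12.759   7.085  -4.962  1.00  1.00           C
ATOM      4  O   GLY A   1      13.720   7.063  -5.734  1.00  1.00           O
END
"""


@pytest.fixture
def gly_structure() -> Structure:
    return parse_pdb(GLY_PDB)


@pytest.fixture
def extended_hexapeptide() -> Structure:
    return build_backbone([ResidueSpec("GLY", -140.0, 135.0) for _ in range(6)])


@pytest.fixture
def type1_turn_structure() -> Structure:
    """Four-residue window with canonical Type I turn angles at i+1/i+2."""
    return build_backbone(
        [
            ResidueSpec("GLY", -140.0, 135.0),
            ResidueSpec("SER", -60.0, -30.0),
            ResidueSpec("GLY", -90.0, 0.0),
            ResidueSpec("GLY", -140.0, 135.0),
        ]
    )


def random_rigid_transform(rng: np.random.Generator):
    """Uniform random rotation (QR of a Gaussian matrix) plus translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-50.0, 50.0, size=3)
    return q, t


def apply_rigid(structure: Structure, rot: np.ndarray, shift: np.ndarray) -> Structure:
    for res in structure.residues():
        for a in res.atoms:
            a.coord = rot @ a.coord + shift
    structure.ions = [(e, rot @ np.asarray(c) + shift) for e, c in structure.ions]
    return structure
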