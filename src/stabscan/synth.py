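"""Synthetic polypeptide builder with planted, ground-truth features.

Structures are grown from internal coordinates (natural-extension reference
frames) using a single table of ideal covalent geometry, so prescribed
backbone dihedrals are reproduced exactly by construction. On top of the
builder sit fixture factories that plant features with known geometry — an
acidic/basic residue pair at a prescribed minimum charged-atom distance, a
buried or exposed residue, a toy metal coordination shell — and record the
ground truth in a :class:`PlantedFeatureLog` so downstream detectors can be
tested without any external structure.

Side chains come from rigid canonical templates (extended chi angles), not a
rotamer library; that is sufficient for planting distances and for computing
self-consistent solvent-accessibility references.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .geometry import dihedral, place_atom
from .structure import Atom, Residue, Structure

__all__ = [
    "ResidueSpec",
    "PlantedFeature",
    "PlantedFeatureLog",
    "build_backbone",
    "attach_sidechain",
    "build_peptide",
    "make_salt_bridge_fixture",
    "make_burial_fixture",
    "make_coordination_fixture",
    "SIDE_CHAIN_TEMPLATES",
]

# Ideal backbone covalent geometry (Engh–Huber-style values). Any
# self-consistent set works here: every consumer measures angles or distances
# relative to what the builder itself produced.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

# Charged side-chain atoms used for planting ion-pair distances.
ACID_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASE_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}


@dataclass
class ResidueSpec:
    """Backbone dihedrals for one residue of a :func:`build_backbone` spec.

    ``phi`` of the first residue and ``psi`` of the last are ignored (they are
    undefined at chain termini); ``omega`` applies to the peptide bond
    preceding the residue.
    """

    name: str = "GLY"
    phi: Optional[float] = None
    psi: Optional[float] = None
    omega: float = 180.0


@dataclass
class PlantedFeature:
    kind: str  # salt_bridge | long_range_pair | turn | buried_residue | coordination_shell
    residues: list[str]
    target: Optional[float] = None
    achieved: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "residues": list(self.residues),
            "target": self.target,
            "achieved": self.achieved,
        }


@dataclass
class PlantedFeatureLog:
    features: list[PlantedFeature] = field(default_factory=list)

    def add(self, *args, **kwargs) -> None:
        self.features.append(PlantedFeature(*args, **kwargs))

    def of_kind(self, kind: str) -> list[PlantedFeature]:
        return [f for f in self.features if f.kind == kind]

    def to_json(self) -> str:
        return json.dumps([f.as_dict() for f in self.features], indent=2, sort_keys=True)


def _normalize_spec(spec: Sequence) -> list[ResidueSpec]:
    out = []
    for item in spec:
        if isinstance(item, ResidueSpec):
            out.append(item)
        else:
            name, phi, psi = item[0], item[1], item[2]
            omega = item[3] if len(item) > 3 else 180.0
            out.append(ResidueSpec(name=name, phi=phi, psi=psi, omega=omega))
    return out


def build_backbone(spec: Sequence, chain_id: str = "A", start_number: int = 1) -> Structure:
    """Build backbone N/CA/C/O coordinates realizing the given phi/psi/omega.

    Measuring the dihedrals of the result returns the spec angles to floating
    point accuracy (the chain is grown by sequential natural extension, so the
    prescribed torsions enter the coordinates exactly).
    """
    residues = _normalize_spec(spec)
    if len(residues) < 2:
        raise ValueError("a backbone needs at least 2 residues")

    coords: list[dict[str, np.ndarray]] = []
    # first residue in a canonical frame: N at origin, CA on +x, C in the xy-plane
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    theta = np.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})

    for i in range(1, len(residues)):
        prev = coords[i - 1]
        psi_prev = residues[i - 1].psi
        if psi_prev is None:
            raise ValueError(f"residue {i - 1}: psi required for chain extension")
        n = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca = place_atom(prev["CA"], prev["C"], n, BOND_N_CA, ANGLE_C_N_CA, residues[i].omega)
        phi = residues[i].phi
        if phi is None:
            if i != len(residues) - 1:
                raise ValueError(f"residue {i}: phi required for interior residues")
            phi = -140.0  # terminal phi is unconstrained; any value closes the chain
        c = place_atom(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        coords.append({"N": n, "CA": ca, "C": c})

    # carbonyl O in the peptide plane, anti to the next residue's N
    for i, rc in enumerate(coords):
        psi = residues[i].psi
        if psi is None:
            psi = 135.0  # last residue: unconstrained, extended-like placement
        o_torsion = psi + 180.0
        if o_torsion > 180.0:
            o_torsion -= 360.0
        rc["O"] = place_atom(rc["N"], rc["CA"], rc["C"], BOND_C_O, ANGLE_CA_C_O, o_torsion)

    structure = Structure()
    chain: list[Residue] = []
    for i, (rspec, rc) in enumerate(zip(residues, coords)):
        atoms = [
            Atom(name=name, element=name[0], coord=rc[name])
            for name in ("N", "CA", "C", "O")
        ]
        chain.append(
            Residue(
                chain_id=chain_id,
                number=start_number + i,
                name=rspec.name.upper(),
                atoms=atoms,
            )
        )
    structure.chains[chain_id] = chain
    return structure


# Side-chain templates: (atom_name, (ref_a, ref_b, ref_c), bond, angle, torsion)
# where the new atom is bonded to ref_c and the torsion is a-b-c-new. CB is
# placed off the backbone frame (tetrahedral improper N-C-CA-CB); chains are
# extended with canonical (mostly anti) chi angles.
_CB = ("CB", ("N", "C", "CA"), 1.530, 110.5, 122.6)

SIDE_CHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "ALA": [_CB],
    "SER": [_CB, ("OG", ("N", "CA", "CB"), 1.417, 110.8, 180.0)],
    "CYS": [_CB, ("SG", ("N", "CA", "CB"), 1.808, 114.4, 180.0)],
    "THR": [
        _CB,
        ("OG1", ("N", "CA", "CB"), 1.433, 109.6, 180.0),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, -60.0),
    ],
    "VAL": [
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.521, 110.5, 180.0),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, -60.0),
    ],
    "LEU": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, 180.0),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, 60.0),
    ],
    "ILE": [
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, 180.0),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, -60.0),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, 180.0),
    ],
    "ASP": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, 180.0),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, 0.0),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, 180.0),
    ],
    "ASN": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, 180.0),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, 0.0),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, 180.0),
    ],
    "GLU": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.530, 114.1, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, 0.0),
        ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, 180.0),
    ],
    "GLN": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.530, 114.1, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, 0.0),
        ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, 180.0),
    ],
    "LYS": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.530, 114.1, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.530, 111.3, 180.0),
        ("CE", ("CB", "CG", "CD"), 1.530, 111.3, 180.0),
        ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, 180.0),
    ],
    "ARG": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.530, 114.1, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.530, 111.3, 180.0),
        ("NE", ("CB", "CG", "CD"), 1.461, 112.0, 180.0),
        ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, 180.0),
        ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
    ],
    "MET": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.530, 114.1, 180.0),
        ("SD", ("CA", "CB", "CG"), 1.803, 112.7, 180.0),
        ("CE", ("CB", "CG", "SD"), 1.791, 100.9, 180.0),
    ],
    "PHE": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.384, 120.7, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.384, 120.7, -90.0),
        ("CE1", ("CB", "CG", "CD1"), 1.382, 120.7, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.382, 120.7, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
    ],
    "TYR": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.512, 113.9, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.389, 120.8, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.389, 120.8, -90.0),
        ("CE1", ("CB", "CG", "CD1"), 1.382, 121.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.382, 121.2, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0),
    ],
    "HIS": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.497, 113.8, 180.0),
        ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.356, 131.1, -90.0),
        ("CE1", ("CB", "CG", "ND1"), 1.321, 109.3, 180.0),
        ("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0),
    ],
    "TRP": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.498, 113.6, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.433, 126.7, -90.0),
        ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
        ("CE2", ("CG", "CD1", "NE1"), 1.370, 109.0, 0.0),
        ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, 180.0),
        ("CZ2", ("CD1", "NE1", "CE2"), 1.394, 130.1, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.8, 180.0),
        ("CH2", ("CD2", "CE3", "CZ3"), 1.368, 121.1, 0.0),
    ],
    "PRO": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.492, 104.5, 30.0),
        ("CD", ("CA", "CB", "CG"), 1.503, 106.1, -35.0),
    ],
}


def attach_sidechain(structure: Structure, residue, rotamer: str = "canonical") -> Structure:
    """Attach side-chain atoms to a backbone residue from an ideal template.

    ``residue`` is a :class:`Residue` of ``structure`` or a residue number.
    The structure is modified in place and returned.
    """
    if rotamer != "canonical":
        raise ValueError(f"unknown rotamer template {rotamer!r}")
    if isinstance(residue, Residue):
        res = residue
    else:
        res = structure.find(int(residue))
        if res is None:
            raise ValueError(f"residue {residue} not found in structure")
    if res.name == "GLY":
        raise ValueError("glycine has no side chain to attach")
    template = SIDE_CHAIN_TEMPLATES.get(res.name)
    if template is None:
        raise ValueError(f"no side-chain template for residue type {res.name!r}")
    if not res.has_backbone:
        raise ValueError(f"residue {res.label} lacks backbone N/CA/C")
    placed = {a.name: a.coord for a in res.atoms}
    for name, (ra, rb, rc), bond, angle, torsion in template:
        if name in placed:
            continue
        coord = place_atom(placed[ra], placed[rb], placed[rc], bond, angle, torsion)
        placed[name] = coord
        element = "S" if name.startswith("S") else name[0]
        res.atoms.append(Atom(name=name, element=element, coord=coord))
    return structure


def build_peptide(
    sequence: Sequence[str],
    phi: float = -140.0,
    psi: float = 135.0,
    chain_id: str = "A",
    start_number: int = 1,
) -> Structure:
    """Extended peptide with side chains: convenience over backbone + templates."""
    spec = [ResidueSpec(name=aa, phi=phi, psi=psi) for aa in sequence]
    structure = build_backbone(spec, chain_id=chain_id, start_number=start_number)
    for res in structure.chains[chain_id]:
        if res.name != "GLY":
            attach_sidechain(structure, res)
    return structure


def _translate(structure: Structure, shift: np.ndarray) -> None:
    for res in structure.residues():
        for a in res.atoms:
            a.coord = a.coord + shift


def _rotate(structure: Structure, rot: np.ndarray) -> None:
    for res in structure.residues():
        for a in res.atoms:
            a.coord = rot @ a.coord


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v (Rodrigues)."""
    c = float(np.dot(u, v))
    axis = np.cross(u, v)
    s = float(np.linalg.norm(axis))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis orthogonal to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    axis /= s
    kmat = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + s * kmat + (1.0 - c) * (kmat @ kmat)


def _merge(target: Structure, other: Structure) -> None:
    for cid, residues in other.chains.items():
        target.chains.setdefault(cid, []).extend(residues)
    target.ions.extend(other.ions)


def make_salt_bridge_fixture(
    acid: str = "ASP",
    base: str = "LYS",
    target_min_on: float = 3.5,
    seed: int = 0,
) -> tuple[Structure, PlantedFeatureLog]:
    """Two short peptides with the minimum acidic-O to basic-N distance planted.

    The fragments are rigidly separated along a fixed axis and the separation
    is solved (scalar root find) so the minimum distance over all charged
    oxygen-nitrogen atom pairs equals ``target_min_on`` to well below the
    0.05 A contract. Raises if the target is outside [2.5, 15] A or can only
    be met with an inter-fragment steric clash (< 2.5 A heavy-atom contact).
    """
    acid = acid.upper()
    base = base.upper()
    if acid not in ACID_ATOMS:
        raise ValueError(f"acidic residue must be ASP or GLU, got {acid!r}")
    if base not in BASE_ATOMS:
        raise ValueError(f"basic residue must be LYS or ARG, got {base!r}")
    if not 2.5 <= target_min_on <= 15.0:
        raise ValueError("target minimum O-N distance must be within [2.5, 15] A")

    frag_a = build_peptide(["GLY", acid, "GLY"], chain_id="A", start_number=1)
    frag_b = build_peptide(["GLY", base, "GLY"], chain_id="B", start_number=1)

    acid_res = frag_a.chains["A"][1]
    base_res = frag_b.chains["B"][1]
    n_base_names = list(BASE_ATOMS[base])

    # orient the second fragment head-on: its charged tip points back toward
    # the first fragment's charged tip, bodies on opposite sides
    a_xyz = np.array([a.coord for _, a in frag_a.atoms()])
    o_coords = np.array([acid_res.coord(n) for n in ACID_ATOMS[acid]])
    w = o_coords.mean(axis=0) - a_xyz.mean(axis=0)
    w /= np.linalg.norm(w)
    b_xyz = np.array([a.coord for _, a in frag_b.atoms()])
    n_coords = np.array([base_res.coord(n) for n in n_base_names])
    v = n_coords.mean(axis=0) - b_xyz.mean(axis=0)
    v /= np.linalg.norm(v)
    rot = _rotation_between(v, -w)
    _rotate(frag_b, rot)
    n_tip = rot @ n_coords.mean(axis=0)
    _translate(frag_b, o_coords.mean(axis=0) + (target_min_on + 2.0) * w - n_tip)

    def min_on(t: float) -> float:
        n_now = np.array([base_res.coord(n) for n in n_base_names]) + t * w
        d = np.linalg.norm(o_coords[:, None, :] - n_now[None, :, :], axis=-1)
        return float(d.min())

    lo = -(target_min_on + 6.0)
    ts = np.linspace(lo, 25.0, 1201)
    vals = np.array([min_on(t) for t in ts])
    below = np.nonzero(vals < target_min_on)[0]
    if below.size == 0:
        raise ValueError("unreachable target: fragments cannot approach closely enough")
    t_lo = float(ts[below[-1]])
    t_star = brentq(lambda t: min_on(t) - target_min_on, t_lo, 25.0, xtol=1e-10)

    _translate(frag_b, t_star * w)
    achieved = min_on(0.0)  # frag_b already shifted

    # steric clash guard across fragments
    a_xyz = np.array([a.coord for _, a in frag_a.atoms()])
    b_xyz = np.array([a.coord for _, a in frag_b.atoms()])
    gap = np.linalg.norm(a_xyz[:, None, :] - b_xyz[None, :, :], axis=-1).min()
    if gap < 2.5 - 1e-6:
        raise ValueError(
            f"unreachable target: steric clash ({gap:.2f} A < 2.5 A) at the "
            f"requested O-N separation"
        )

    fixture = Structure()
    _merge(fixture, frag_a)
    _merge(fixture, frag_b)
    kind = "salt_bridge" if target_min_on <= 4.0 else (
        "long_range_pair" if target_min_on <= 8.0 else "non_pair"
    )
    log = PlantedFeatureLog()
    log.add(kind, [f"A/{acid_res.label}", f"B/{base_res.label}"], target_min_on, achieved)
    return fixture, log


def make_burial_fixture(
    center: str = "ASP",
    shell: int = 30,
    shell_radius: float = 7.0,
    seed: int = 0,
) -> tuple[Structure, PlantedFeatureLog]:
    """A central residue surrounded by ``shell`` dummy glycine blockers.

    ``shell=0`` leaves the central side chain maximally exposed; a dense shell
    (>= 30 residues at 6-8 A) occludes it to well under 5% relative solvent
    accessibility. Blocker residues are placed on two staggered spheres around
    the side-chain centroid in deterministic quasi-uniform directions.
    """
    if shell < 0:
        raise ValueError("shell count must be >= 0")
    center = center.upper()
    spec = [ResidueSpec(center, -140.0, 135.0), ResidueSpec("GLY", -140.0, 135.0)]
    structure = build_backbone(spec[:2], chain_id="A")
    # keep only the central residue: a lone residue with backbone + side chain
    structure.chains["A"] = structure.chains["A"][:1]
    center_res = structure.chains["A"][0]
    if center != "GLY":
        attach_sidechain(structure, center_res)

    sc = center_res.side_chain_atoms()
    centroid = np.mean([a.coord for a in sc], axis=0)

    rng = np.random.default_rng(seed)
    blockers: list[Residue] = []
    for k in range(shell):
        u = _fibonacci_direction(k, max(shell, 1))
        radius = max(shell_radius - 1.6 * (k % 3), 4.5)
        ca = centroid + radius * u
        # local tangent frame; the dummy's atoms are spread tangentially in a
        # cross so each blocker occludes a wide patch of the shell
        t1 = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(u, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(u, t1)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        v1 = np.cos(ang) * t1 + np.sin(ang) * t2
        v2 = -np.sin(ang) * t1 + np.cos(ang) * t2
        atoms = [
            Atom("CA", "C", ca),
            Atom("N", "N", ca + 1.9 * v1),
            Atom("C", "C", ca - 1.9 * v1),
            Atom("O", "O", ca + 1.9 * v2),
            Atom("CB", "C", ca - 1.9 * v2),
        ]
        blockers.append(
            Residue(chain_id="B", number=k + 1, name="ALA", atoms=atoms)
        )
    if blockers:
        structure.chains["B"] = blockers

    log = PlantedFeatureLog()
    log.add(
        "buried_residue",
        [f"A/{center_res.label}"],
        target=float(shell),
        achieved=float(shell),
    )
    return structure, log


def _fibonacci_direction(k: int, n: int) -> np.ndarray:
    """k-th of n quasi-uniform unit vectors on the sphere (golden spiral)."""
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(max(0.0, 1.0 - z * z))
    phi = 2.0 * np.pi * k / golden
    return np.array([r * np.cos(phi), r * np.sin(phi), z])


# near-octahedral directions for coordination shells
_OCTAHEDRAL = [
    np.array([1.0, 0.0, 0.0]),
    np.array([-1.0, 0.0, 0.0]),
    np.array([0.0, 1.0, 0.0]),
    np.array([0.0, -1.0, 0.0]),
    np.array([0.0, 0.0, 1.0]),
    np.array([0.0, 0.0, -1.0]),
    np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0),
    np.array([-1.0, -1.0, -1.0]) / np.sqrt(3.0),
]


def make_coordination_fixture(
    n_ligands: int,
    ion_distance: float = 2.4,
    seed: int = 0,
) -> tuple[Structure, np.ndarray, PlantedFeatureLog]:
    """Toy metal coordination shell: oxygen ligands on a sphere around an ion.

    ``n_ligands`` carboxylate oxygens (OD1 of host aspartate-like residues)
    are placed at ``ion_distance`` from a calcium ion at the origin along
    near-octahedral directions; the remaining host atoms point radially
    outward so only the planted oxygens fall inside a coordination cutoff.
    """
    if not 1 <= n_ligands <= 8:
        raise ValueError("n_ligands must be within [1, 8]")
    ion = np.zeros(3)
    structure = Structure()
    chain: list[Residue] = []
    for k in range(n_ligands):
        u = _OCTAHEDRAL[k]
        t1 = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(u, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        d = ion_distance
        atoms = [
            Atom("OD1", "O", ion + d * u),
            Atom("CG", "C", ion + (d + 1.25) * u),
            Atom("OD2", "O", ion + (d + 1.25) * u + 1.25 * t1),
            Atom("CB", "C", ion + (d + 2.45) * u),
            Atom("CA", "C", ion + (d + 3.70) * u),
            Atom("N", "N", ion + (d + 3.70) * u + 1.46 * t1),
            Atom("C", "C", ion + (d + 4.95) * u),
            Atom("O", "O", ion + (d + 6.00) * u),
        ]
        chain.append(Residue(chain_id="A", number=k + 1, name="ASP", atoms=atoms))
    structure.chains["A"] = chain
    structure.ions.append(("CA", ion.copy()))

    log = PlantedFeatureLog()
    log.add(
        "coordination_shell",
        [f"A/{r.label}" for r in chain],
        target=ion_distance,
        achieved=ion_distance,
    )
    return structure, ion, log
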