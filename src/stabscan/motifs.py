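"""Beta-turn detection and typing, i+1 proline design, calcium-site analysis.

A beta turn is four consecutive residues i..i+3 with the chain reversing on
itself: C-alpha(i) to C-alpha(i+3) at most 7.0 A apart and the central two
residues not part of an alpha-helix. The turn type is assigned from the
(phi, psi) of residues i+1 and i+2 against the classical ideal-angle
taxonomy (Type I, II, their mirror-image primes, VIII), with the standard
tolerance of +/-30 degrees on every angle and a single angle allowed up to
+/-45; windows matching no ideal quadruple are Type IV (other). Proline at
the i+1 position of a Type I turn reduces the entropy of the unfolded state,
which is why Type I turns without a native proline there are substitution
candidates; residues with a structural role (calcium ligands, the catalytic
triad of a subtilase) must be excluded explicitly by the caller.

Calcium sites are described by their coordination shell: every oxygen within
a cutoff (default 3.0 A, generous for the typical 2.3-2.6 A Ca-O distance)
of a supplied ion coordinate, labelled as side-chain oxygen (OD*/OE*/OG*/OH)
or main-chain carbonyl. Grafting a homolog's site into the target is
verified by comparing the expected ligand set of the graft against the shell
observed in a model carrying the graft mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import GeometryError, dihedral, distance
from .structure import Residue, Structure, residue_id

__all__ = [
    "BetaTurn",
    "CaSite",
    "CaLigand",
    "GraftSpec",
    "GraftReport",
    "MutationCandidate",
    "detect_beta_turns",
    "classify_turn_type",
    "propose_proline_candidates",
    "analyze_ca_site",
    "check_graft",
]

CA_DISTANCE_CUTOFF = 7.0
CA_O_CUTOFF = 3.0
PEPTIDE_BOND_MAX = 2.0  # C(i)-N(i+1) continuity check, ideal 1.33 A

# ideal (phi1, psi1, phi2, psi2) per turn type; match order is fixed for
# determinism, Type IV is the fallback
TURN_IDEALS: list[tuple[str, tuple[float, float, float, float]]] = [
    ("I", (-60.0, -30.0, -90.0, 0.0)),
    ("II", (-60.0, 120.0, 80.0, 0.0)),
    ("I'", (60.0, 30.0, 90.0, 0.0)),
    ("II'", (60.0, -120.0, -80.0, 0.0)),
    ("VIII", (-60.0, -30.0, -120.0, 120.0)),
]
TURN_TOLERANCE = 30.0
TURN_SINGLE_TOLERANCE = 45.0

HELIX_PHI_PSI = (-63.0, -42.0)
HELIX_WINDOW = 40.0
HELIX_MIN_RUN = 4


@dataclass
class BetaTurn:
    residues: tuple[Residue, Residue, Residue, Residue]
    phi1: float
    psi1: float
    phi2: float
    psi2: float
    ca_distance: float
    type: str

    @property
    def i1(self) -> Residue:
        """The i+1 residue — the proline-substitution position of Type I turns."""
        return self.residues[1]

    @property
    def label(self) -> str:
        r = self.residues
        return f"{r[0].label}..{r[3].label}"


@dataclass
class CaLigand:
    residue: Residue
    atom_name: str
    distance: float
    role: str  # "side_chain" | "main_chain_carbonyl"


@dataclass
class CaSite:
    label: str
    ion_coord: np.ndarray
    cutoff: float
    ligands: list[CaLigand]

    def ligand_triples(self) -> set[tuple[int, str, str]]:
        return {(lg.residue.number, lg.atom_name, lg.role) for lg in self.ligands}


@dataclass
class GraftSpec:
    """Expected outcome of transplanting a homolog's calcium site."""

    mutations: list[tuple[int, str, str]]  # (position, wt, mut) one-letter codes
    expected_ligands: list[tuple[int, str, str]]  # (position, atom name, role)
    donor_note: str = ""


@dataclass
class GraftReport:
    satisfied: list[tuple[int, str, str]]
    missing: list[tuple[int, str, str]]
    extra: list[tuple[int, str, str]]

    @property
    def verdict(self) -> str:
        return "satisfied" if not self.missing else "unsatisfied"


@dataclass
class MutationCandidate:
    """A proposed point mutation with its design rationale category."""

    position: int
    wt: str
    mut: str
    category: str
    rationale: str = ""

    @property
    def notation(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"


def wrap_angle_diff(a: float, b: float) -> float:
    """Absolute angular difference on the circle, degrees in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def classify_turn_type(phi1: float, psi1: float, phi2: float, psi2: float) -> str:
    """Turn type from the central dihedrals; 'IV' when no ideal set matches."""
    angles = (phi1, psi1, phi2, psi2)
    for name, ideal in TURN_IDEALS:
        devs = sorted(wrap_angle_diff(a, b) for a, b in zip(angles, ideal))
        if devs[-1] <= TURN_SINGLE_TOLERANCE and devs[-2] <= TURN_TOLERANCE:
            return name
    return "IV"


def _consecutive_runs(chain: Sequence[Residue]) -> list[list[Residue]]:
    """Split a chain into runs of backbone-complete, peptide-bonded residues."""
    runs: list[list[Residue]] = []
    current: list[Residue] = []
    for res in chain:
        if not (res.is_amino_acid and res.has_backbone):
            if current:
                runs.append(current)
            current = []
            continue
        if current:
            prev = current[-1]
            c_prev = prev.coord("C")
            n_here = res.coord("N")
            bonded = (
                c_prev is not None
                and n_here is not None
                and distance(c_prev, n_here) <= PEPTIDE_BOND_MAX
                and not res.insertion_code
                and not prev.insertion_code
            )
            if not bonded:
                runs.append(current)
                current = []
        current.append(res)
    if current:
        runs.append(current)
    return runs


def _backbone_dihedrals(run: Sequence[Residue]) -> list[tuple[Optional[float], Optional[float]]]:
    out: list[tuple[Optional[float], Optional[float]]] = []
    for i, res in enumerate(run):
        phi = psi = None
        try:
            if i > 0:
                phi = dihedral(
                    run[i - 1].coord("C"), res.coord("N"), res.coord("CA"), res.coord("C")
                )
            if i < len(run) - 1:
                psi = dihedral(
                    res.coord("N"), res.coord("CA"), res.coord("C"), run[i + 1].coord("N")
                )
        except GeometryError:
            phi = psi = None
        out.append((phi, psi))
    return out


def _helical_mask(dihedrals: list[tuple[Optional[float], Optional[float]]]) -> list[bool]:
    """Residues in an alpha-helical run of at least HELIX_MIN_RUN."""
    near = []
    for phi, psi in dihedrals:
        near.append(
            phi is not None
            and psi is not None
            and wrap_angle_diff(phi, HELIX_PHI_PSI[0]) <= HELIX_WINDOW
            and wrap_angle_diff(psi, HELIX_PHI_PSI[1]) <= HELIX_WINDOW
        )
    mask = [False] * len(near)
    i = 0
    while i < len(near):
        if near[i]:
            j = i
            while j < len(near) and near[j]:
                j += 1
            if j - i >= HELIX_MIN_RUN:
                for k in range(i, j):
                    mask[k] = True
            i = j
        else:
            i += 1
    return mask


def detect_beta_turns(
    structure: Structure,
    ca_cutoff: float = CA_DISTANCE_CUTOFF,
    helix_veto: bool = True,
) -> list[BetaTurn]:
    """All four-residue windows forming beta turns, typed; overlaps reported.

    Windows with incomplete backbones are skipped. With ``helix_veto`` (the
    default) windows whose central residues sit inside an alpha-helical run
    are not called turns, mirroring how secondary-structure-aware annotators
    treat helical stretches.
    """
    turns: list[BetaTurn] = []
    for chain in structure.chains.values():
        for run in _consecutive_runs(chain):
            if len(run) < 4:
                continue
            dihedrals = _backbone_dihedrals(run)
            helical = _helical_mask(dihedrals) if helix_veto else [False] * len(run)
            for i in range(len(run) - 3):
                window = tuple(run[i : i + 4])
                ca_i = window[0].coord("CA")
                ca_i3 = window[3].coord("CA")
                d = distance(ca_i, ca_i3)
                if d > ca_cutoff:
                    continue
                phi1, psi1 = dihedrals[i + 1]
                phi2, psi2 = dihedrals[i + 2]
                if None in (phi1, psi1, phi2, psi2):
                    continue
                if helical[i + 1] and helical[i + 2]:
                    continue
                turns.append(
                    BetaTurn(
                        residues=window,
                        phi1=phi1,
                        psi1=psi1,
                        phi2=phi2,
                        psi2=psi2,
                        ca_distance=d,
                        type=classify_turn_type(phi1, psi1, phi2, psi2),
                    )
                )
    return turns


def propose_proline_candidates(
    turns: list[BetaTurn],
    exclusions: Optional[set[int]] = None,
) -> list[MutationCandidate]:
    """X -> Pro candidates at the i+1 position of Type I turns.

    Turns whose i+1 residue is already proline, or whose position is in the
    exclusion set (calcium ligands, catalytic residues, ...), are skipped.
    Candidates are deduplicated by position and sorted by position.
    """
    exclusions = exclusions or set()
    seen: set[int] = set()
    out: list[MutationCandidate] = []
    for turn in turns:
        if turn.type != "I":
            continue
        res = turn.i1
        if res.name == "PRO":
            continue
        if res.number in exclusions or res.number in seen:
            continue
        seen.add(res.number)
        out.append(
            MutationCandidate(
                position=res.number,
                wt=res.one_letter,
                mut="P",
                category="turn_pro",
                rationale=(
                    f"i+1 position of Type I beta turn {turn.label}; proline "
                    "lowers the entropy of the unfolded state"
                ),
            )
        )
    out.sort(key=lambda c: c.position)
    return out


_SIDE_CHAIN_O_PREFIXES = ("OD", "OE", "OG", "OH")


def analyze_ca_site(
    structure: Structure,
    ion_coord,
    cutoff: float = CA_O_CUTOFF,
    label: str = "Ca",
) -> CaSite:
    """Coordination shell of a calcium ion: all oxygens within the cutoff.

    Ligands are sorted by distance. An empty shell is a valid result, not an
    error.
    """
    ion = np.asarray(ion_coord, dtype=float)
    if ion.shape != (3,) or not np.all(np.isfinite(ion)):
        raise ValueError("ion coordinate must be a finite 3-vector")
    ligands: list[CaLigand] = []
    for res, atom in structure.atoms():
        if atom.element.upper() != "O":
            continue
        d = distance(atom.coord, ion)
        if d > cutoff:
            continue
        if atom.name.startswith(_SIDE_CHAIN_O_PREFIXES):
            role = "side_chain"
        else:
            role = "main_chain_carbonyl"
        ligands.append(CaLigand(residue=res, atom_name=atom.name, distance=d, role=role))
    ligands.sort(key=lambda lg: lg.distance)
    return CaSite(label=label, ion_coord=ion, cutoff=cutoff, ligands=ligands)


def check_graft(site: CaSite, spec: GraftSpec, structure: Structure) -> GraftReport:
    """Compare a graft's expected ligand set against an observed shell.

    The verdict is "satisfied" iff every expected (residue, atom, role)
    triple is observed; extra observed ligands do not spoil it. Raises if a
    spec position is absent from the structure.
    """
    for pos, _, _ in spec.mutations:
        if structure.find(pos) is None:
            raise ValueError(f"graft mutation position {pos} absent from structure")
    for pos, _, _ in spec.expected_ligands:
        if structure.find(pos) is None:
            raise ValueError(f"expected ligand position {pos} absent from structure")

    observed = site.ligand_triples()
    expected = set(spec.expected_ligands)
    satisfied = sorted(expected & observed)
    missing = sorted(expected - observed)
    extra = sorted(observed - expected)
    return GraftReport(satisfied=satisfied, missing=missing, extra=extra)
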