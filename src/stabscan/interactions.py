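"""Ion-pair detection, ionic networks, exposure annotation, unpaired basics.

An ion pair is an acidic residue (Asp/Glu) and a basic residue (Lys/Arg)
whose minimum charged-atom distance — carboxylate oxygens OD1/OD2/OE1/OE2
against side-chain nitrogens NZ (Lys) or NE/NH1/NH2 (Arg) — falls within a
cutoff. Pairs at or under 4.0 A are salt bridges; pairs above that but at or
under 8.0 A are long-range ion pairs (both boundaries inclusive). A residue
pair is counted once however many atom contacts it makes. Histidine is not
counted as basic by default (subtilase charge accounting in this package
follows Lys/Arg-only conventions); pass ``include_his=True`` to add
ND1/NE2 contacts.

Ionic networks are connected components of the residue graph whose edges are
ion pairs; a component qualifies as a network when it carries at least two
pairs, so a census like "13 pairs of which 12 form 3 networks" is expressible
with one isolated pair left over.

Exposure follows the relative-accessibility convention: the RASA of a pair
is the arithmetic mean of its two members' RASA and a pair (or residue) with
RASA >= 20% is solvent-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .structure import Residue, Structure, residue_id

__all__ = [
    "IonPair",
    "IonicNetwork",
    "detect_ion_pairs",
    "build_ionic_networks",
    "annotate_exposure",
    "unpaired_basic_residues",
    "ACIDIC_ATOMS",
    "BASIC_ATOMS",
]

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
HIS_ATOMS = ("ND1", "NE2")

SALT_BRIDGE_CUTOFF = 4.0
LONG_RANGE_CUTOFF = 8.0
EXPOSURE_THRESHOLD = 20.0


@dataclass
class IonPair:
    """One acidic-basic residue pair with its minimum charged-atom distance."""

    acidic: Residue
    basic: Residue
    min_distance: float
    category: str  # "salt_bridge" | "long_range"
    pair_rasa: Optional[float] = None
    exposed: Optional[bool] = None  # None until exposure is annotated / unknown

    @property
    def label(self) -> str:
        return f"{self.basic.label}-{self.acidic.label}"

    def involves(self, res: Residue) -> bool:
        rid = residue_id(res)
        return residue_id(self.acidic) == rid or residue_id(self.basic) == rid


@dataclass
class IonicNetwork:
    """Connected group of residues linked by two or more ion pairs."""

    members: list[Residue]
    pairs: list[IonPair]

    @property
    def label(self) -> str:
        return "-".join(r.label for r in self.members)


def _charged_atoms(res: Residue, names: Iterable[str]) -> np.ndarray:
    coords = [res.coord(n) for n in names]
    coords = [c for c in coords if c is not None]
    return np.asarray(coords) if coords else np.empty((0, 3))


def detect_ion_pairs(
    structure: Structure,
    salt_cutoff: float = SALT_BRIDGE_CUTOFF,
    long_cutoff: float = LONG_RANGE_CUTOFF,
    include_his: bool = False,
) -> list[IonPair]:
    """All acidic-basic residue pairs within ``long_cutoff``, categorized.

    The distance of a pair is the minimum over its side-chain oxygen-nitrogen
    atom distances. Residues whose charged side-chain atoms are absent from
    the model are skipped. Output is sorted by (acidic resnum, basic resnum).
    """
    if not 0 < salt_cutoff <= long_cutoff:
        raise ValueError("cutoffs must satisfy 0 < salt_cutoff <= long_cutoff")
    basic_atom_map = dict(BASIC_ATOMS)
    if include_his:
        basic_atom_map["HIS"] = HIS_ATOMS

    acidic = []
    basic = []
    for res in structure.amino_acids():
        if res.name in ACIDIC_ATOMS:
            xyz = _charged_atoms(res, ACIDIC_ATOMS[res.name])
            if len(xyz):
                acidic.append((res, xyz))
        if res.name in basic_atom_map:
            xyz = _charged_atoms(res, basic_atom_map[res.name])
            if len(xyz):
                basic.append((res, xyz))

    pairs: list[IonPair] = []
    for ares, axyz in acidic:
        for bres, bxyz in basic:
            d = np.linalg.norm(axyz[:, None, :] - bxyz[None, :, :], axis=-1).min()
            if d <= long_cutoff:
                category = "salt_bridge" if d <= salt_cutoff else "long_range"
                pairs.append(IonPair(ares, bres, float(d), category))
    pairs.sort(
        key=lambda p: (
            p.acidic.chain_id,
            p.acidic.number,
            p.acidic.insertion_code,
            p.basic.chain_id,
            p.basic.number,
            p.basic.insertion_code,
        )
    )
    return pairs


def build_ionic_networks(pairs: list[IonPair]) -> tuple[list[IonicNetwork], list[IonPair]]:
    """Group pairs into ionic networks (components with >= 2 pairs).

    Returns ``(networks, singleton_pairs)``; singletons are pairs whose
    component contains only themselves. Networks are sorted by their smallest
    member residue number; the result is independent of input pair order.
    """
    graph = nx.Graph()
    res_by_id: dict[tuple, Residue] = {}
    for p in pairs:
        ai, bi = residue_id(p.acidic), residue_id(p.basic)
        res_by_id[ai] = p.acidic
        res_by_id[bi] = p.basic
        graph.add_edge(ai, bi)

    networks: list[IonicNetwork] = []
    singletons: list[IonPair] = []
    for component in nx.connected_components(graph):
        comp_pairs = [
            p
            for p in pairs
            if residue_id(p.acidic) in component and residue_id(p.basic) in component
        ]
        if len(comp_pairs) >= 2:
            members = sorted(
                (res_by_id[rid] for rid in component),
                key=lambda r: (r.chain_id, r.number, r.insertion_code),
            )
            networks.append(IonicNetwork(members=members, pairs=comp_pairs))
        else:
            singletons.extend(comp_pairs)
    networks.sort(key=lambda n: (n.members[0].chain_id, n.members[0].number))
    singletons.sort(key=lambda p: (p.acidic.chain_id, p.acidic.number))
    return networks, singletons


def annotate_exposure(
    pairs: list[IonPair],
    rasa: dict[tuple, float],
    threshold: float = EXPOSURE_THRESHOLD,
) -> list[IonPair]:
    """Set pair_rasa (mean of member RASA) and the inclusive exposure flag.

    Pairs with a member missing from the RASA mapping are flagged
    unknown-exposure (``exposed`` stays None).
    """
    for p in pairs:
        ra = rasa.get(residue_id(p.acidic))
        rb = rasa.get(residue_id(p.basic))
        if ra is None or rb is None:
            p.pair_rasa = None
            p.exposed = None
            continue
        p.pair_rasa = float(ra + rb) / 2.0
        p.exposed = bool(p.pair_rasa >= threshold)
    return pairs


def unpaired_basic_residues(
    structure: Structure, pairs: list[IonPair]
) -> list[Residue]:
    """Lys/Arg residues participating in no ion pair, sorted by number."""
    paired = {residue_id(p.basic) for p in pairs}
    out = [
        res
        for res in structure.amino_acids()
        if res.name in BASIC_ATOMS and residue_id(res) not in paired
    ]
    out.sort(key=lambda r: (r.chain_id, r.number, r.insertion_code))
    return out
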