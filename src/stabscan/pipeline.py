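"""Candidate generation and aggregation: surface Asp/Glu scan, multi-tool
consensus selection, and the unified stabilization-candidate report.

The consensus stage mirrors the common practice of running several stability
predictors (physics-based and learned) on the same structure and keeping
the mutations that at least ``k`` of them agree on (default k = 2): single
tools over-predict, agreement filters noise. Predictor outputs are consumed
as a minimal TSV interchange format with columns ``wt``, ``position``,
``mut`` — one row per proposed mutation per tool — because each web tool's
native export varies by version.

The surface-acidic scan proposes X -> Asp/Glu substitutions that could form
a new ion pair with an existing basic residue. Feasibility is a permissive
C-beta-anchored reach test, not a rotamer search: the candidate's C-beta must
lie within ``long_cutoff + reach`` of a charged nitrogen of the partner,
where reach is the C-beta-to-carboxylate-oxygen span of the proposed residue
in an extended rotamer (Asp 2.5 A, Glu 3.9 A). Candidate lists are meant for
human triage, so a superset of workable designs is the intended behaviour.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .interactions import (
    BASIC_ATOMS,
    IonicNetwork,
    IonPair,
    unpaired_basic_residues,
)
from .motifs import BetaTurn, CaSite, GraftReport, MutationCandidate
from .structure import Residue, Structure, residue_id

__all__ = [
    "MutationRecord",
    "SurfaceAcidicCandidate",
    "parse_predictor_tables",
    "consensus_select",
    "scan_surface_acidic_candidates",
    "generate_report",
    "PredictorTableError",
]

AA1 = set("ACDEFGHIKLMNPQRSTVWY")

# C-beta to farthest carboxylate oxygen, extended rotamer
REACH = {"ASP": 2.5, "GLU": 3.9}
ONE_LETTER = {"ASP": "D", "GLU": "E"}
SCAN_EXCLUDED_TYPES = {"GLY", "PRO", "CYS"}


class PredictorTableError(ValueError):
    """Malformed or inconsistent predictor mutation table."""


@dataclass
class MutationRecord:
    """A point mutation and the set of predictor tools proposing it."""

    position: int
    wt: str
    mut: str
    tools: set[str] = field(default_factory=set)
    category: str = "consensus"

    def __post_init__(self) -> None:
        if self.wt == self.mut:
            raise ValueError(f"wild-type and substitution identical at {self.position}")

    @property
    def support(self) -> int:
        return len(self.tools)

    @property
    def notation(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"


@dataclass
class SurfaceAcidicCandidate:
    """An exposed residue proposed for Asp/Glu substitution near a basic partner."""

    target: Residue
    proposed: str  # "ASP" | "GLU"
    partner: Residue
    cb_to_charge: float
    partner_unpaired: bool

    @property
    def notation(self) -> str:
        return f"{self.target.one_letter}{self.target.number}{ONE_LETTER[self.proposed]}"


def parse_predictor_tables(
    streams: Iterable[tuple[str, str]],
) -> list[MutationRecord]:
    """Merge per-tool mutation tables into records with tool support.

    Each entry of ``streams`` is ``(tool name, TSV text)`` with required
    header columns wt, position, mut. Records are merged across tools by
    (position, wt, mut); two tools disagreeing on the wild type of the same
    position is a consistency error.
    """
    merged: dict[tuple[int, str, str], MutationRecord] = {}
    wt_at_position: dict[int, tuple[str, str]] = {}  # position -> (wt, tool)
    seen_tools: set[str] = set()
    for tool, text in streams:
        if tool in seen_tools:
            raise PredictorTableError(f"duplicate tool name {tool!r}")
        seen_tools.add(tool)
        try:
            df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
        except Exception as exc:
            raise PredictorTableError(f"{tool}: unreadable TSV ({exc})") from exc
        missing = {"wt", "position", "mut"} - set(df.columns)
        if missing:
            raise PredictorTableError(
                f"{tool}: missing required column(s) {sorted(missing)}"
            )
        for row_idx, row in df.iterrows():
            lineno = row_idx + 2  # header is line 1
            wt = str(row["wt"]).strip().upper()
            mut = str(row["mut"]).strip().upper()
            try:
                position = int(str(row["position"]).strip())
            except ValueError:
                raise PredictorTableError(
                    f"{tool}: line {lineno}: malformed position {row['position']!r}"
                ) from None
            if wt not in AA1 or mut not in AA1:
                raise PredictorTableError(
                    f"{tool}: line {lineno}: malformed amino acid code "
                    f"{wt!r}/{mut!r}"
                )
            prior = wt_at_position.get(position)
            if prior is not None and prior[0] != wt:
                raise PredictorTableError(
                    f"wild-type conflict at position {position}: "
                    f"{prior[1]} says {prior[0]}, {tool} says {wt}"
                )
            wt_at_position[position] = (wt, tool)
            key = (position, wt, mut)
            rec = merged.get(key)
            if rec is None:
                rec = MutationRecord(position=position, wt=wt, mut=mut)
                merged[key] = rec
            rec.tools.add(tool)
    return sorted(merged.values(), key=lambda r: (r.position, r.mut))


def consensus_select(
    records: Sequence[MutationRecord], min_support: int = 2
) -> list[MutationRecord]:
    """Records proposed by at least ``min_support`` tools.

    Sorted by (support descending, position ascending, substitution
    alphabetical).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    kept = [r for r in records if r.support >= min_support]
    kept.sort(key=lambda r: (-r.support, r.position, r.mut))
    return kept


def scan_surface_acidic_candidates(
    structure: Structure,
    rasa: dict[tuple, float],
    pairs: list[IonPair],
    rasa_threshold: float = 20.0,
    long_cutoff: float = 8.0,
    reach: Optional[dict[str, float]] = None,
    exclusions: Optional[set[int]] = None,
) -> list[SurfaceAcidicCandidate]:
    """Exposed residues that could pair with a basic residue if made acidic.

    For every Lys/Arg partner B and every candidate residue T: T must be
    exposed (RASA >= threshold), not Gly/Pro/Cys, not already acidic, not in
    the exclusion set (catalytic residues etc.), and its C-beta must lie
    within ``long_cutoff + reach[proposed]`` of B's nearest charged nitrogen.
    Partners outside every existing ion pair carry ``partner_unpaired=True``.
    Output is deduplicated and sorted by (partner resnum, distance).
    """
    reach = dict(REACH) if reach is None else reach
    exclusions = exclusions or set()
    unpaired_ids = {residue_id(r) for r in unpaired_basic_residues(structure, pairs)}

    basics = []
    for res in structure.amino_acids():
        if res.name not in BASIC_ATOMS:
            continue
        coords = [res.coord(n) for n in BASIC_ATOMS[res.name]]
        coords = [c for c in coords if c is not None]
        if coords:
            basics.append((res, np.asarray(coords)))

    out: list[SurfaceAcidicCandidate] = []
    seen: set[tuple[tuple, str, tuple]] = set()
    for partner, n_xyz in basics:
        for target in structure.amino_acids():
            rid = residue_id(target)
            if rid == residue_id(partner):
                continue
            if target.name in SCAN_EXCLUDED_TYPES or target.name in ("ASP", "GLU"):
                continue
            if target.number in exclusions:
                continue
            r = rasa.get(rid)
            if r is None or r < rasa_threshold:
                continue
            cb = target.coord("CB")
            if cb is None:
                continue
            d = float(np.linalg.norm(n_xyz - cb, axis=1).min())
            for proposed, extra in reach.items():
                if d <= long_cutoff + extra:
                    key = (rid, proposed, residue_id(partner))
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(
                        SurfaceAcidicCandidate(
                            target=target,
                            proposed=proposed,
                            partner=partner,
                            cb_to_charge=d,
                            partner_unpaired=residue_id(partner) in unpaired_ids,
                        )
                    )
    out.sort(
        key=lambda c: (c.partner.chain_id, c.partner.number, c.cb_to_charge, c.notation)
    )
    return out


def _pair_dict(p: IonPair) -> dict:
    return {
        "acidic": p.acidic.label,
        "basic": p.basic.label,
        "min_distance": round(p.min_distance, 4),
        "category": p.category,
        "pair_rasa": None if p.pair_rasa is None else round(p.pair_rasa, 3),
        "exposed": p.exposed,
    }


def generate_report(
    ion_pairs: Optional[list[IonPair]] = None,
    networks: Optional[list[IonicNetwork]] = None,
    singleton_pairs: Optional[list[IonPair]] = None,
    unpaired_basics: Optional[list[Residue]] = None,
    turns: Optional[list[BetaTurn]] = None,
    turn_pro_candidates: Optional[list[MutationCandidate]] = None,
    ca_sites: Optional[list[CaSite]] = None,
    graft_reports: Optional[list[tuple[str, GraftReport]]] = None,
    surface_acidic: Optional[list[SurfaceAcidicCandidate]] = None,
    consensus: Optional[list[MutationRecord]] = None,
    parameters: Optional[dict] = None,
) -> dict:
    """Assemble the unified, deterministic design report.

    At least one stage output must be supplied. The returned dict is
    JSON-serializable with stable ordering; every candidate carries its
    category and rationale, and the parameters block records the settings the
    stages ran with so any entry can be recomputed from the report alone.
    """
    sections = (
        ion_pairs,
        networks,
        singleton_pairs,
        unpaired_basics,
        turns,
        turn_pro_candidates,
        ca_sites,
        graft_reports,
        surface_acidic,
        consensus,
    )
    if all(s is None for s in sections):
        raise ValueError("generate_report needs at least one stage output")

    report: dict = {"parameters": dict(sorted((parameters or {}).items()))}
    if ion_pairs is not None:
        report["ion_pairs"] = [_pair_dict(p) for p in ion_pairs]
        report["n_salt_bridges"] = sum(
            1 for p in ion_pairs if p.category == "salt_bridge"
        )
        report["n_long_range"] = sum(1 for p in ion_pairs if p.category == "long_range")
    if networks is not None:
        report["ionic_networks"] = [
            {
                "members": [r.label for r in n.members],
                "n_pairs": len(n.pairs),
                "pairs": [_pair_dict(p) for p in n.pairs],
            }
            for n in networks
        ]
    if singleton_pairs is not None:
        report["singleton_pairs"] = [_pair_dict(p) for p in singleton_pairs]
    if unpaired_basics is not None:
        report["unpaired_basic_residues"] = [r.label for r in unpaired_basics]
    if turns is not None:
        report["beta_turns"] = [
            {
                "window": t.label,
                "type": t.type,
                "phi1": round(t.phi1, 2),
                "psi1": round(t.psi1, 2),
                "phi2": round(t.phi2, 2),
                "psi2": round(t.psi2, 2),
                "ca_distance": round(t.ca_distance, 3),
            }
            for t in turns
        ]
    candidates: list[dict] = []
    if turn_pro_candidates is not None:
        candidates.extend(
            {
                "mutation": c.notation,
                "category": c.category,
                "rationale": c.rationale,
                "provenance": "beta-turn scan",
            }
            for c in turn_pro_candidates
        )
    if ca_sites is not None:
        report["ca_sites"] = [
            {
                "label": s.label,
                "cutoff": s.cutoff,
                "ligands": [
                    {
                        "residue": lg.residue.label,
                        "atom": lg.atom_name,
                        "role": lg.role,
                        "distance": round(lg.distance, 3),
                    }
                    for lg in s.ligands
                ],
            }
            for s in ca_sites
        ]
    if graft_reports is not None:
        report["graft_verdicts"] = [
            {
                "graft": name,
                "verdict": rep.verdict,
                "satisfied": [list(t) for t in rep.satisfied],
                "missing": [list(t) for t in rep.missing],
                "extra": [list(t) for t in rep.extra],
            }
            for name, rep in graft_reports
        ]
    if surface_acidic is not None:
        candidates.extend(
            {
                "mutation": c.notation,
                "category": "surface_acidic",
                "rationale": (
                    f"exposed residue within reach of {c.partner.label} "
                    f"(Cb-to-N {c.cb_to_charge:.2f} A"
                    + (", partner unpaired)" if c.partner_unpaired else ")")
                ),
                "provenance": "surface acidic scan",
            }
            for c in surface_acidic
        )
    if consensus is not None:
        candidates.extend(
            {
                "mutation": r.notation,
                "category": r.category,
                "rationale": f"predicted by {r.support} tools: "
                + ", ".join(sorted(r.tools)),
                "provenance": "predictor consensus",
            }
            for r in consensus
        )
    if candidates:
        report["candidates"] = candidates
    return report


def report_to_json(report: dict) -> str:
    """Byte-stable JSON rendering of a report."""
    return json.dumps(report, indent=2, sort_keys=True)


def report_candidates_frame(report: dict) -> pd.DataFrame:
    """Candidate section of a report as a table (for TSV export)."""
    return pd.DataFrame(report.get("candidates", []))
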