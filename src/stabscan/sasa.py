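"""Solvent-accessible surface area (sphere-point method) and relative
solvent accessibility.

The algorithm is the classic sphere-point construction: each heavy atom is
expanded by the probe radius (water, 1.4 A by default) and sampled with a
deterministic quasi-uniform spiral point set; the accessible area is the
fraction of points outside every neighbour's expanded sphere times the
sphere area. There is no random number generator anywhere, so results are
bitwise reproducible.

Relative solvent accessibility (RASA) of a residue is the ratio of its
side-chain accessible area to a per-residue-type "random coil" reference,
expressed as a percent. The reference is the side-chain area of X in an
extended Gly-X-Gly tripeptide built internally (phi = -140, psi = 135,
canonical rotamer), which makes RASA self-consistent with this package's own
area definition; values may therefore exceed 100% for conformations more
exposed than the reference. Residues with RASA >= 20% are conventionally
called solvent-exposed. Glycine, having no side chain, uses its C-alpha as
the side-chain proxy.

Bound metal ions are excluded from both the surface and the occlusion by
default (the ``include_ions`` switch adds them), since ion placement is an
explicit modelling input rather than part of the polymer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .structure import BACKBONE_ATOMS, Structure, residue_id

__all__ = [
    "SasaResult",
    "compute_sasa",
    "compute_rasa",
    "reference_area",
    "VDW_RADII",
    "ION_RADII",
]

# Heavy-atom van der Waals radii, A. Radius conventions differ between SASA
# programs; this fixed table is shipped so results are self-consistent.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

ION_RADII = {"CA": 2.31, "ZN": 1.39, "MG": 1.73, "NA": 2.27, "K": 2.75}

DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960


@dataclass
class SasaResult:
    """Per-atom and per-residue accessible areas plus RASA bookkeeping."""

    atom_keys: list[tuple]  # (residue_id, atom_name)
    atom_areas: np.ndarray  # A^2, aligned with atom_keys
    residue_names: dict[tuple, str]  # residue_id -> 3-letter code
    residue_total: dict[tuple, float]  # A^2
    residue_sidechain: dict[tuple, float]  # A^2
    probe_radius: float
    n_sphere_points: int
    rasa: dict[tuple, float] = field(default_factory=dict)  # percent
    rasa_undefined: set = field(default_factory=set)

    @property
    def total_area(self) -> float:
        return float(self.atom_areas.sum())

    def to_frame(self):
        """Per-residue table (chain, resnum, icode, resname, areas, RASA)."""
        import pandas as pd

        rows = []
        for rid, name in self.residue_names.items():
            chain, num, icode = rid
            rows.append(
                {
                    "chain": chain,
                    "resnum": num,
                    "icode": icode,
                    "resname": name,
                    "area_total": self.residue_total[rid],
                    "area_sidechain": self.residue_sidechain[rid],
                    "rasa_pct": self.rasa.get(rid, float("nan")),
                }
            )
        return pd.DataFrame(rows)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (golden-spiral construction)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    phi = 2.0 * np.pi * k / golden
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_radius(element: str, resname: str, atom_name: str) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        r = ION_RADII.get(element.upper())
    if r is None:
        raise ValueError(
            f"no van der Waals radius for atom {atom_name} "
            f"(element {element!r}) in residue {resname}"
        )
    return r


def compute_sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    include_ions: bool = False,
) -> SasaResult:
    """Sphere-point solvent-accessible surface area of every heavy atom.

    Raises if the structure has no atoms or an atom's element has no entry in
    the radius table.
    """
    keys: list[tuple] = []
    coords: list[np.ndarray] = []
    radii: list[float] = []
    residue_names: dict[tuple, str] = {}
    for res in structure.residues():
        rid = residue_id(res)
        residue_names[rid] = res.name
        for a in res.atoms:
            keys.append((rid, a.name))
            coords.append(a.coord)
            radii.append(_atom_radius(a.element, res.name, a.name))
    n_polymer = len(keys)
    if include_ions:
        for i, (elem, coord) in enumerate(structure.ions):
            keys.append((("", -(i + 1), ""), elem))
            coords.append(np.asarray(coord, dtype=float))
            radii.append(_atom_radius(elem, elem, elem))
    if not keys:
        raise ValueError("structure has no heavy atoms")

    xyz = np.asarray(coords)
    expanded = np.asarray(radii) + probe
    unit = sphere_points(n_points)

    tree = cKDTree(xyz)
    max_r = float(expanded.max())
    areas = np.empty(len(keys))
    for i in range(len(keys)):
        ri = expanded[i]
        pts = xyz[i] + ri * unit
        neighbors = tree.query_ball_point(xyz[i], ri + max_r)
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            rj = expanded[j]
            if np.linalg.norm(xyz[j] - xyz[i]) >= ri + rj:
                continue
            d2 = np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j])
            accessible &= d2 >= rj * rj
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * ri * ri * accessible.sum() / n_points

    residue_total: dict[tuple, float] = {rid: 0.0 for rid in residue_names}
    residue_sidechain: dict[tuple, float] = {rid: 0.0 for rid in residue_names}
    for (rid, atom_name), area in zip(keys[:n_polymer], areas[:n_polymer]):
        residue_total[rid] += area
        resname = residue_names[rid]
        is_side = (
            atom_name == "CA" if resname == "GLY" else atom_name not in BACKBONE_ATOMS
        )
        if is_side:
            residue_sidechain[rid] += area

    return SasaResult(
        atom_keys=keys,
        atom_areas=areas,
        residue_names=residue_names,
        residue_total=residue_total,
        residue_sidechain=residue_sidechain,
        probe_radius=probe,
        n_sphere_points=n_points,
    )


@lru_cache(maxsize=None)
def reference_area(
    resname: str,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> float:
    """Side-chain area of X in an extended Gly-X-Gly tripeptide, A^2.

    Computed once per residue type and cached; deterministic. For glycine the
    C-alpha proxy convention applies.
    """
    from .synth import SIDE_CHAIN_TEMPLATES, build_peptide

    resname = resname.upper()
    if resname != "GLY" and resname not in SIDE_CHAIN_TEMPLATES:
        raise ValueError(f"no reference conformation for residue type {resname!r}")
    tri = build_peptide(["GLY", resname, "GLY"])
    result = compute_sasa(tri, probe=probe, n_points=n_points)
    center = residue_id(tri.chains["A"][1])
    return result.residue_sidechain[center]


def compute_rasa(result: SasaResult) -> dict[tuple, float]:
    """Fill and return per-residue RASA (percent) on a :class:`SasaResult`.

    RASA = 100 * side-chain area / reference area of the residue type.
    Non-glycine residues with no side-chain atoms present have undefined RASA:
    they are flagged in ``result.rasa_undefined`` and excluded from the
    returned mapping (and hence from any exposure call downstream).
    """
    # which residues actually carry side-chain atoms in the input
    has_side: dict[tuple, bool] = {rid: False for rid in result.residue_names}
    for rid, atom_name in result.atom_keys:
        if rid not in has_side:
            continue
        resname = result.residue_names[rid]
        if resname == "GLY":
            has_side[rid] = has_side[rid] or atom_name == "CA"
        elif atom_name not in BACKBONE_ATOMS:
            has_side[rid] = True

    rasa: dict[tuple, float] = {}
    for rid, resname in result.residue_names.items():
        if not has_side[rid]:
            result.rasa_undefined.add(rid)
            continue
        ref = reference_area(resname, result.probe_radius, result.n_sphere_points)
        rasa[rid] = float(100.0 * result.residue_sidechain[rid] / ref)
    result.rasa = rasa
    return rasa
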