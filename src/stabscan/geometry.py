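"""Exact 3-D geometry primitives: distances, torsion angles, and atom placement.

All coordinates are in angstroms, all angles in degrees. The torsion
convention is the standard IUPAC right-handed one: a trans (antiperiplanar)
arrangement measures +180 deg, a cis (synperiplanar) arrangement 0 deg, and
the returned range is (-180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = ["distance", "dihedral", "place_atom", "GeometryError"]

# p2 == p3 or a collinear bounding triple leaves the torsion undefined;
# cross products below this norm are treated as degenerate.
_COLLINEAR_EPS = 1e-8


class GeometryError(ValueError):
    """Raised for degenerate geometric input (collinear torsion frames etc.)."""


def distance(a, b) -> float:
    """Euclidean distance between two 3-vectors, in angstroms."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise GeometryError("distance requires finite coordinates")
    return float(np.linalg.norm(a - b))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, range (-180, 180].

    Raises :class:`GeometryError` if p2 == p3 or either bounding triple is
    collinear, in which case the torsion is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < _COLLINEAR_EPS:
        raise GeometryError("undefined dihedral: central atoms coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_EPS or np.linalg.norm(n2) < _COLLINEAR_EPS:
        raise GeometryError("undefined dihedral: collinear atom triple")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    # atan2 yields (-180, 180]; -180 can still appear from rounding
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given three reference atoms (natural extension / NeRF).

    D is positioned so that ``|C-D| = bond``, the B-C-D angle equals ``angle``
    (degrees) and the torsion A-B-C-D equals ``torsion`` (degrees, IUPAC
    convention consistent with :func:`dihedral`).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _COLLINEAR_EPS:
        raise GeometryError("cannot place atom: reference atoms are collinear")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local
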