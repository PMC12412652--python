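"""Low-level vector geometry: dihedrals, internal-coordinate atom placement.

These helpers operate on plain numpy 3-vectors and are shared by the
structure data model (backbone dihedral annotation), the synthetic helix
generator (NeRF chain building) and the geometry filters.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dihedral", "angle", "place_atom", "fibonacci_sphere"]


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral angle a-b-c-d in degrees, in (-180, 180].

    Uses the atan2 formulation, which is numerically stable near 0 and 180.
    """
    b0 = np.asarray(a, float) - np.asarray(b, float)
    b1 = np.asarray(c, float) - np.asarray(b, float)
    b2 = np.asarray(d, float) - np.asarray(c, float)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    # fold -180 exactly onto +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c in degrees."""
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    theta: float,
    torsion: float,
) -> np.ndarray:
    """Place atom D given atoms A, B, C via internal coordinates (NeRF).

    D is at distance ``bond`` from C, with angle B-C-D ``theta`` (degrees)
    and dihedral A-B-C-D ``torsion`` (degrees).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    th = np.radians(theta)
    tor = np.radians(torsion)
    bc = c - b
    bc = bc / np.sqrt(bc @ bc)
    ab = b - a
    n = np.array(
        [
            ab[1] * bc[2] - ab[2] * bc[1],
            ab[2] * bc[0] - ab[0] * bc[2],
            ab[0] * bc[1] - ab[1] * bc[0],
        ]
    )
    n = n / np.sqrt(n @ n)
    m = np.array(
        [
            n[1] * bc[2] - n[2] * bc[1],
            n[2] * bc[0] - n[0] * bc[2],
            n[0] * bc[1] - n[1] * bc[0],
        ]
    )
    d_local = np.array(
        [
            -bond * np.cos(th),
            bond * np.sin(th) * np.cos(tor),
            bond * np.sin(th) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere (golden-spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + 5**0.5)
    theta = golden * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
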