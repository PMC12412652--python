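"""Coarse internal-coordinate side-chain builder and polar-atom typing.

Side chains are built from backbone N/CA/C with idealized bond lengths and
tetrahedral-ish angles, parameterized by at most two variable chi angles
(chi3+ fixed extended). The topology is a simplified single-path-plus-short-
branches reading of each amino acid: good enough to give the steric,
hydrogen-bond and burial terms real donor/acceptor geometry, not a
crystallographic rotamer library.
"""

from __future__ import annotations

import numpy as np

from .geometry import place_atom
from .structio import Residue

__all__ = [
    "N_CHI",
    "build_sidechain",
    "set_residue_identity",
    "DONORS",
    "ACCEPTORS",
    "is_donor",
    "is_acceptor",
    "VDW_RADII",
    "vdw_radius",
]

# torsion spec: ("chi", k, offset_deg) -> chi_k + offset; ("fix", deg) -> constant
# entries: (name, (a3, a2, a1), bond, angle, torsion_spec); atoms placed in order
_CB = ("CB", ("N", "C", "CA"), 1.52, 110.5, ("fix", 122.6))

_TOPOLOGY: dict[str, list] = {
    "ALA": [_CB],
    "GLY": [],
    "SER": [_CB, ("OG", ("N", "CA", "CB"), 1.42, 110.8, ("chi", 1, 0.0))],
    "CYS": [_CB, ("SG", ("N", "CA", "CB"), 1.81, 113.8, ("chi", 1, 0.0))],
    "THR": [
        _CB,
        ("OG1", ("N", "CA", "CB"), 1.43, 109.6, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -120.0)),
    ],
    "VAL": [
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 120.0)),
    ],
    "LEU": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.53, 116.3, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 2, 120.0)),
    ],
    "ILE": [
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.53, 110.4, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -120.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.52, 113.9, ("chi", 2, 0.0)),
    ],
    "MET": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
        ("SD", ("CA", "CB", "CG"), 1.80, 112.7, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "SD"), 1.79, 100.9, ("fix", 180.0)),
    ],
    "PRO": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.49, 104.5, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.50, 106.1, ("chi", 2, 0.0)),
    ],
    "PHE": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.8, ("fix", 180.0)),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.8, ("fix", 180.0)),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, ("fix", 0.0)),
    ],
    "TYR": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.51, 113.9, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.8, ("fix", 180.0)),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.8, ("fix", 180.0)),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, ("fix", 0.0)),
        ("OH", ("CD1", "CE1", "CZ"), 1.38, 119.9, ("fix", 180.0)),
    ],
    "TRP": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.50, 113.6, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.37, 126.9, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.43, 126.8, ("chi", 2, 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, ("fix", 180.0)),
        ("CE2", ("CB", "CG", "CD2"), 1.41, 107.2, ("fix", 180.0)),
        ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.4, ("fix", 180.0)),
    ],
    "ASP": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.4, ("chi", 2, 0.0)),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.4, ("chi", 2, 180.0)),
    ],
    "ASN": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 112.7, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, ("chi", 2, 0.0)),
        ("ND2", ("CA", "CB", "CG"), 1.33, 116.5, ("chi", 2, 180.0)),
    ],
    "GLU": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.4, ("fix", 0.0)),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.4, ("fix", 180.0)),
    ],
    "GLN": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, ("fix", 0.0)),
        ("NE2", ("CB", "CG", "CD"), 1.33, 116.5, ("fix", 180.0)),
    ],
    "LYS": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "CD"), 1.52, 111.3, ("fix", 180.0)),
        ("NZ", ("CG", "CD", "CE"), 1.49, 111.9, ("fix", 180.0)),
    ],
    "ARG": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
        ("NE", ("CB", "CG", "CD"), 1.46, 112.0, ("fix", 180.0)),
        ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, ("fix", 180.0)),
        ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, ("fix", 0.0)),
        ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, ("fix", 180.0)),
    ],
    "HIS": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.49, 113.8, ("chi", 1, 0.0)),
        ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.35, 131.0, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.32, 109.2, ("fix", 180.0)),
        ("NE2", ("CB", "CG", "CD2"), 1.37, 107.2, ("fix", 180.0)),
    ],
}

#: number of variable chi angles per residue type
N_CHI: dict[str, int] = {
    name: max([spec[1] for _, _, _, _, spec in topo if spec[0] == "chi"] + [0])
    for name, topo in _TOPOLOGY.items()
}

# heavy-atom polar typing (heavy-atom H-bond criterion; no explicit hydrogens).
# Backbone: N donor (except PRO), O acceptor -- handled by callers via names.
DONORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "ASN": ("ND2",), "GLN": ("NE2",), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"), "TRP": ("NE1",),
}
ACCEPTORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",), "GLN": ("OE1",), "HIS": ("ND1", "NE2"),
}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}


def vdw_radius(atom_name: str) -> float:
    stripped = atom_name.strip("0123456789")
    return VDW_RADII.get(stripped[0] if stripped else "C", 1.70)


def is_donor(res_name: str, atom_name: str) -> bool:
    if atom_name == "N" and res_name != "PRO":
        return True
    return atom_name in DONORS.get(res_name, ())


def is_acceptor(res_name: str, atom_name: str) -> bool:
    if atom_name == "O":
        return True
    return atom_name in ACCEPTORS.get(res_name, ())


def build_sidechain(
    n: np.ndarray, ca: np.ndarray, c: np.ndarray, res_name: str, chis: tuple[float, ...] = ()
) -> dict[str, np.ndarray]:
    """Build side-chain heavy atoms for ``res_name`` from backbone N/CA/C.

    ``chis`` supplies the variable chi angles (degrees); missing ones default
    to 180 (extended). Returns atom-name -> coordinate, excluding backbone.
    """
    topo = _TOPOLOGY[res_name]
    atoms: dict[str, np.ndarray] = {"N": np.asarray(n, float), "CA": np.asarray(ca, float), "C": np.asarray(c, float)}
    built: dict[str, np.ndarray] = {}
    for name, (a3, a2, a1), bond, ang, spec in topo:
        if spec[0] == "chi":
            k, offset = spec[1], spec[2]
            chi = chis[k - 1] if len(chis) >= k else 180.0
            torsion = chi + offset
        else:
            torsion = spec[1]
        pos = place_atom(atoms[a3], atoms[a2], atoms[a1], bond, ang, torsion)
        atoms[name] = pos
        built[name] = pos
    return built


def set_residue_identity(
    res: Residue, new_name: str, chis: tuple[float, ...] = ()
) -> None:
    """Mutate a residue in place: swap identity and rebuild the side chain.

    Backbone atoms (N, CA, C, O) are preserved; all side-chain atoms are
    replaced by the coarse ideal-geometry build.
    """
    backbone = {k: v for k, v in res.atoms.items() if k in ("N", "CA", "C", "O")}
    if not all(k in backbone for k in ("N", "CA", "C")):
        raise ValueError(f"residue {res.number} lacks backbone atoms")
    side = build_sidechain(backbone["N"], backbone["CA"], backbone["C"], new_name, chis)
    res.name = new_name
    res.atoms = {**backbone, **side}
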