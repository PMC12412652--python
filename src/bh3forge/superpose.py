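"""Rigid-body least-squares superposition (Kabsch) and selection-based RMSD.

Atom pairing between two selections is positional: residues are paired in
selection order, atoms by name within each residue pair; atoms present in
only one member are dropped (never imputed) and the number actually aligned
is reported.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .structio import Structure, BACKBONE_ATOMS

__all__ = ["Selection", "Superposition", "kabsch", "rmsd_between", "parse_selection"]

_ATOM_SUBSETS = {
    "CA": ("CA",),
    "backbone": BACKBONE_ATOMS,
    "heavy": None,  # all heavy atoms
}


@dataclasses.dataclass
class Selection:
    """Chain + inclusive author-numbered residue ranges + atom subset."""

    chain: str
    ranges: list[tuple[int, int]]
    atoms: str = "CA"  # one of CA | backbone | heavy

    def __post_init__(self) -> None:
        if self.atoms not in _ATOM_SUBSETS:
            raise ValueError(f"unknown atom subset {self.atoms!r}")
        if not self.ranges:
            raise ValueError("empty residue range list")
        for lo, hi in self.ranges:
            if hi < lo:
                raise ValueError(f"bad range {lo}-{hi}")

    def gather(self, s: Structure) -> list[tuple[int, str, np.ndarray]]:
        """(residue number, atom name, coord) triples in residue order."""
        subset = _ATOM_SUBSETS[self.atoms]
        out = []
        for res in s.chain(self.chain).polymer():
            if not any(lo <= res.number <= hi for lo, hi in self.ranges):
                continue
            names = subset if subset is not None else [
                n for n in res.atoms if not n.startswith("H")
            ]
            for name in names:
                if name in res.atoms:
                    out.append((res.number, name, res.atoms[name]))
        return out


@dataclasses.dataclass
class Superposition:
    """Optimal proper rotation + translation mapping P onto Q, with RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def __post_init__(self) -> None:
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-8:
            raise ValueError(f"rotation is not proper orthogonal (det={det})")


def kabsch(P: np.ndarray, Q: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of paired point sets P -> Q.

    Returns the global minimizer of RMSD over proper rotations and
    translations (SVD solution with reflection guard). Collinear/degenerate
    point sets are solved but produce a warning, since the rotation about the
    degenerate axis is then arbitrary.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching n x 3 arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired points")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1.0):
        warnings.warn("degenerate (collinear) point set in superposition", stacklevel=2)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return Superposition(R, t, rmsd, n)


def rmsd_between(
    sA: Structure, selA: Selection, sB: Structure, selB: Selection
) -> Superposition:
    """Superpose selection A onto selection B and report the RMSD.

    Residues are paired by order within each selection; atoms by name within
    each residue pair. Unpaired residues/atoms are dropped and the aligned
    count is carried on the result.
    """
    atomsA = selA.gather(sA)
    atomsB = selB.gather(sB)

    # group by residue in order
    def by_res(atoms):
        groups: list[dict[str, np.ndarray]] = []
        order: list[int] = []
        for num, name, xyz in atoms:
            if not order or order[-1] != num:
                order.append(num)
                groups.append({})
            groups[-1][name] = xyz
        return groups

    gA, gB = by_res(atomsA), by_res(atomsB)
    P, Q = [], []
    for ra, rb in zip(gA, gB):
        for name in ra:
            if name in rb:
                P.append(ra[name])
                Q.append(rb[name])
    if not P:
        raise ValueError("zero paired atoms between selections")
    return kabsch(np.array(P), np.array(Q))


def parse_selection(text: str) -> Selection:
    """Parse the CLI mini-grammar ``chain:first-last[,first-last...]:subset``.

    Example: ``A:90-141:CA``. Subset is one of CA, backbone, heavy.
    """
    parts = text.split(":")
    if len(parts) != 3:
        raise ValueError(f"bad selection {text!r}; expected chain:ranges:subset")
    chain, ranges_text, subset = parts
    ranges = []
    for chunk in ranges_text.split(","):
        lo, _, hi = chunk.partition("-")
        ranges.append((int(lo), int(hi or lo)))
    return Selection(chain, ranges, subset)
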