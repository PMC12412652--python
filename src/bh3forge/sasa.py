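"""Solvent-accessible surface area by sphere-dot (Shrake-Rupley) integration."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .geometry import fibonacci_sphere
from .sidechains import vdw_radius
from .structio import Structure, BACKBONE_ATOMS

__all__ = ["atom_sasa", "sidechain_sasa"]


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_dots: int = 960,
) -> np.ndarray:
    """Per-atom SASA (A^2) over expanded spheres of radius r_i + probe.

    Each atom's sphere carries ``n_dots`` quasi-uniform dots; a dot is
    accessible if it lies outside every neighbouring expanded sphere. The
    returned SASA is the accessible fraction times the expanded-sphere area.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float) + probe
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    dots = fibonacci_sphere(n_dots)
    tree = cKDTree(coords)
    out = np.zeros(n)
    rmax = radii.max()
    for i in range(n):
        neighbours = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax) if j != i]
        pts = coords[i] + radii[i] * dots
        if neighbours:
            nb = np.array(neighbours)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return out


def sidechain_sasa(
    s: Structure,
    probe: float = 2.2,
    n_dots: int = 960,
    chain_id: str | None = None,
) -> dict[tuple[str, int], float]:
    """Per-residue side-chain SASA, keyed (chain id, residue number).

    Computed in the context of the whole input structure (pass an isolated
    chain for monomer-state selection). Side-chain atoms are every heavy
    atom beyond backbone N/CA/C/O; residues with no side-chain atoms (e.g.
    glycine or backbone-only models) fall back to CB, then CA, as an
    exposure proxy.
    """
    atoms = []
    owners = []
    for ch in s.chains:
        for res in ch.polymer():
            for name, xyz in res.atoms.items():
                if name.startswith("H"):
                    continue
                atoms.append((name, xyz))
                owners.append((ch.id, res.number, name))
    if not atoms:
        return {}
    coords = np.array([a[1] for a in atoms])
    radii = np.array([vdw_radius(a[0]) for a in atoms])
    per_atom = atom_sasa(coords, radii, probe=probe, n_dots=n_dots)

    by_res: dict[tuple[str, int], dict[str, float]] = {}
    for (cid, num, name), area in zip(owners, per_atom):
        by_res.setdefault((cid, num), {})[name] = area
    out: dict[tuple[str, int], float] = {}
    for key, areas in by_res.items():
        if chain_id is not None and key[0] != chain_id:
            continue
        side = {n: a for n, a in areas.items() if n not in BACKBONE_ATOMS}
        if side:
            out[key] = float(sum(side.values()))
        elif "CB" in areas:
            out[key] = float(areas["CB"])
        else:
            out[key] = float(areas.get("CA", 0.0))
    return out
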