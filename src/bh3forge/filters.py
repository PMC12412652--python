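"""Design-selection filters: binding energy, shape complementarity, buried
unsatisfied polar atoms, and the peptide-bond omega geometry check.

These are the gates applied to designed complexes before experimental
selection. Thresholds are configuration (the gating values are a modelling
choice, not constants of nature); each filter also stands alone as a
callable metric.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .energy import AtomGroup, EnergyModel, extract_group, residue_group
from .geometry import fibonacci_sphere
from .sasa import atom_sasa
from .sidechains import is_acceptor, is_donor, vdw_radius
from .structio import Structure

__all__ = [
    "FilterThresholds",
    "FilterReport",
    "binding_energy",
    "shape_complementarity",
    "buried_unsat_polar",
    "omega_check",
    "evaluate_filters",
]


@dataclasses.dataclass
class FilterThresholds:
    """Gate values; the omega cutoff defaults to the standard 150 degrees."""

    ddg_max: float = 0.0  # model units; designs must bind at least this well
    sc_min: float = 0.5
    unsat_max: int = 2
    omega_cutoff: float = 150.0  # degrees

    def __post_init__(self) -> None:
        if not 90.0 < self.omega_cutoff < 180.0:
            raise ValueError("omega cutoff must lie in (90, 180)")


@dataclasses.dataclass
class FilterReport:
    binding_energy: float
    sc: float
    buried_unsat: int
    omega_failures: int
    passes: dict[str, bool]

    def __post_init__(self) -> None:
        if not -1.0 <= self.sc <= 1.0:
            raise ValueError("shape complementarity outside [-1, 1]")

    @property
    def overall(self) -> bool:
        return all(self.passes.values())


def _split_chains(complex: Structure, partner_split: str) -> tuple[list[str], list[str]]:
    """Parse a partner split like "B/GH" into two chain-id lists."""
    left, _, right = partner_split.partition("/")
    if not left or not right:
        raise ValueError(f"bad partner split {partner_split!r}; expected e.g. 'B/GH'")
    known = set(complex.chain_ids())
    for cid in left + right:
        if cid not in known:
            raise ValueError(f"chain {cid!r} not in structure")
    return list(left), list(right)


def _substructure(complex: Structure, chain_ids: list[str]) -> Structure:
    return Structure([complex.chain(c).copy() for c in chain_ids])


def binding_energy(
    complex: Structure,
    energy: EnergyModel | None = None,
    partner_split: str | None = None,
    repack: bool = False,
    seed: int = 0,
) -> float:
    """Model binding energy: E(complex) - E(partner A alone) - E(partner B alone).

    Without repacking (default) the separated partners keep their bound
    conformations, so the value reduces to the inter-partner interaction
    terms plus complexation-induced burial penalties; non-contacting
    partners score exactly 0. With ``repack=True`` each isolated partner is
    relaxed by a deterministic repack-only pass before scoring, admitting
    conformational relief of the unbound state.
    """
    energy = energy or EnergyModel()
    if partner_split is None:
        if len(complex.chains) != 2:
            raise ValueError("specify partner_split for structures with != 2 chains")
        partner_split = f"{complex.chains[0].id}/{complex.chains[1].id}"
    left, right = _split_chains(complex, partner_split)
    sub_l = _substructure(complex, left)
    sub_r = _substructure(complex, right)
    if repack:
        from .interface_design import DesignConfig, build_rotamer_set, mc_design

        for sub in (sub_l, sub_r):
            chain0 = sub.chains[0].id
            positions = {r.number for r in sub.chain(chain0).polymer()}
            cfg = DesignConfig(seed=seed, mc_steps=2000)
            rot = build_rotamer_set(sub, chain0, positions, cfg, repack_only=True)
            repacked, _ = mc_design(sub, positions, rot, energy, cfg, chain0)
            sub.chains[:] = repacked.chains
    e_complex = energy.structure_energy(_substructure(complex, left + right))
    return float(e_complex - energy.structure_energy(sub_l) - energy.structure_energy(sub_r))


# -- shape complementarity -------------------------------------------------


def _surface_dots(
    group: AtomGroup, dots_per_atom: int, probe: float = 1.4
) -> tuple[np.ndarray, np.ndarray]:
    """Molecular-surface (contact-patch) dots with outward normals.

    Dots are screened for accessibility on the probe-expanded spheres (the
    probe-centre surface) and then projected back onto the atom's vdW
    sphere. This smooths the crevices between bonded atoms that a raw vdW
    dot surface would expose, approximating the contact portion of the
    solvent-excluded surface.
    """
    sphere = fibonacci_sphere(dots_per_atom)
    tree = cKDTree(group.coords)
    pts, normals = [], []
    rexp = group.radii + probe
    rmax = float(rexp.max())
    for i in range(group.n):
        p = group.coords[i] + rexp[i] * sphere
        nb = [j for j in tree.query_ball_point(group.coords[i], rexp[i] + rmax) if j != i]
        if nb:
            nb = np.array(nb)
            d2 = ((p[:, None, :] - group.coords[nb][None, :, :]) ** 2).sum(axis=2)
            keep = ~(d2 < (rexp[nb] ** 2)[None, :]).any(axis=1)
        else:
            keep = np.ones(len(p), bool)
        pts.append(group.coords[i] + group.radii[i] * sphere[keep])
        normals.append(sphere[keep])
    return np.vstack(pts), np.vstack(normals)


def shape_complementarity(
    complex: Structure,
    partner_split: str,
    dot_density: int = 300,
    band: float = 1.5,
    weight: float = 0.5,
) -> float:
    """Lawrence-Colman-style shape-complementarity statistic in [-1, 1].

    Dots are placed on each partner's exposed van der Waals surface and
    restricted to the interface band (dots within ``band`` A of the closest
    approach to the other partner's surface). Each interface dot is scored
    against its nearest dot on the opposing surface by normal anti-alignment
    damped with exp(-w d^2), w = 0.5 A^-2; the statistic is the mean of the
    two directional medians. Deterministic (fixed dot construction).
    """
    left, right = _split_chains(complex, partner_split)
    ga = extract_group(_substructure(complex, left))
    gb = extract_group(_substructure(complex, right))
    da = cKDTree(gb.coords).query(ga.coords)[0]
    if not (da <= 8.0).any():
        raise ValueError("no contact surface between the partners")
    dots_a, norm_a = _surface_dots(ga, dot_density)
    dots_b, norm_b = _surface_dots(gb, dot_density)

    def interface_mask(dots: np.ndarray, other: AtomGroup) -> np.ndarray:
        # distance from each dot to the other partner's vdW surface
        d, j = cKDTree(other.coords).query(dots)
        surf = d - other.radii[j]
        return surf <= band

    mask_a = interface_mask(dots_a, gb)
    mask_b = interface_mask(dots_b, ga)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("no contact surface between the partners")
    ia, na = dots_a[mask_a], norm_a[mask_a]
    ib, nb = dots_b[mask_b], norm_b[mask_b]

    def directional(dots1, norms1, dots2, norms2) -> float:
        d, j = cKDTree(dots2).query(dots1)
        s = -(norms1 * norms2[j]).sum(axis=1) * np.exp(-weight * d**2)
        return float(np.median(s))

    return 0.5 * (directional(ia, na, ib, nb) + directional(ib, nb, ia, na))


# -- buried unsatisfied polar atoms ---------------------------------------


def buried_unsat_polar(
    complex: Structure,
    partner_split: str | None = None,
    energy: EnergyModel | None = None,
    burial_sasa: float = 0.01,
    probe: float = 1.4,
    n_dots: int = 240,
) -> int:
    """Count interface polar atoms buried upon complexation with no H-bond.

    An N/O donor/acceptor heavy atom counts when (a) its SASA in the complex
    is below ``burial_sasa`` A^2 at probe 1.4 A, (b) it was NOT buried in
    its isolated partner (so burial is a consequence of the interface), and
    (c) it has no H-bond partner under the heavy-atom distance/angle
    criterion (<= 3.5 A, base-donor-acceptor >= 90 deg). A single-chain
    input has no interface and scores 0.
    """
    energy = energy or EnergyModel()
    if partner_split is None:
        if len(complex.chains) < 2:
            return 0
        partner_split = f"{complex.chains[0].id}/{''.join(c.id for c in complex.chains[1:])}"
    left, right = _split_chains(complex, partner_split)

    entries = []  # (partner_index, res_name, atom_name, xyz)
    for pi, ids in enumerate((left, right)):
        for cid in ids:
            for res in complex.chain(cid).polymer():
                for name, xyz in res.atoms.items():
                    if not name.startswith("H"):
                        entries.append((pi, res.name, name, xyz))
    coords = np.array([e[3] for e in entries])
    radii = np.array([vdw_radius(e[2]) for e in entries])
    sasa_complex = atom_sasa(coords, radii, probe=probe, n_dots=n_dots)
    sasa_alone = np.empty_like(sasa_complex)
    for pi in (0, 1):
        idx = np.array([i for i, e in enumerate(entries) if e[0] == pi])
        sasa_alone[idx] = atom_sasa(coords[idx], radii[idx], probe=probe, n_dots=n_dots)

    all_group = extract_group(complex)
    count = 0
    for i, (pi, res_name, name, xyz) in enumerate(entries):
        if not (name[0] in "NO" and (is_donor(res_name, name) or is_acceptor(res_name, name))):
            continue
        if sasa_complex[i] >= burial_sasa or sasa_alone[i] < burial_sasa:
            continue
        single = residue_group(res_name, {name: xyz})
        single.donor[:] = is_donor(res_name, name)
        single.acceptor[:] = is_acceptor(res_name, name)
        # base: nearest heavy atom in the full structure within 2 A
        d = np.linalg.norm(all_group.coords - xyz, axis=1)
        d[d < 1e-9] = np.inf
        jbase = int(np.argmin(d))
        single.base[0] = all_group.coords[jbase]
        env_idx = np.where(d > 1e-9)[0]
        env = AtomGroup(
            all_group.coords[env_idx], all_group.radii[env_idx],
            all_group.donor[env_idx], all_group.acceptor[env_idx],
            all_group.base[env_idx],
        )
        if not energy.has_hbond_partner(0, single, env):
            count += 1
    return count


# -- omega geometry --------------------------------------------------------


def omega_check(
    s: Structure, cutoff_deg: float = 150.0, exempt_cis_proline: bool = True
) -> list[tuple[str, int]]:
    """Residues whose peptide-bond omega deviates from trans beyond the cutoff.

    Residue i fails iff ``abs(omega_i) < cutoff_deg`` (omega_i is the
    dihedral to the following residue; trans is 180). A cis bond preceding a
    proline (omega near 0) is exempt by default, reflecting that cis-Pro is
    a normal geometry rather than a modelling error.
    """
    failures = []
    for ch in s.chains:
        poly = [r for r in ch.polymer() if r.has_backbone()]
        if len(poly) < 2:
            continue
        dihedrals = Structure([ch]).backbone_dihedrals(ch.id)
        for i, info in enumerate(dihedrals[:-1]):
            omega = info["omega"]
            if omega is None:
                continue
            if abs(omega) < cutoff_deg:
                if exempt_cis_proline and poly[i + 1].name == "PRO" and abs(omega) < 30.0:
                    continue
                failures.append((ch.id, poly[i].number))
    return failures


def evaluate_filters(
    complex: Structure,
    partner_split: str,
    thresholds: FilterThresholds,
    energy: EnergyModel | None = None,
) -> FilterReport:
    """Run all four filters and gate against the thresholds."""
    energy = energy or EnergyModel()
    ddg = binding_energy(complex, energy, partner_split)
    try:
        sc = shape_complementarity(complex, partner_split)
    except ValueError:
        sc = -1.0
    unsat = buried_unsat_polar(complex, partner_split, energy)
    omega_failures = len(omega_check(complex, thresholds.omega_cutoff))
    passes = {
        "binding_energy": ddg <= thresholds.ddg_max,
        "sc": sc >= thresholds.sc_min,
        "buried_unsat": unsat <= thresholds.unsat_max,
        "omega": omega_failures == 0,
    }
    return FilterReport(ddg, sc, unsat, omega_failures, passes)
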