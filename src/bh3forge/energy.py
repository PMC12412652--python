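"""Simplified pairwise-decomposable energy model for packing and scoring.

This is a declared four-term surrogate for a full molecular-mechanics
design function, built for pipeline logic rather than thermodynamic
fidelity:

* steric: an 8-4 soft Lennard-Jones on heavy-atom pairs (minimum at the
  summed vdW radii, capped repulsion so the model stays finite in clashes);
* hydrogen bond: a distance Gaussian (optimum 2.9 A, width 0.3 A) times an
  angular gate (base-donor-acceptor >= 90 deg) on heavy donor/acceptor
  pairs, no explicit hydrogens;
* polar burial: a penalty for each polar atom that is buried (neighbour
  count proxy) without any H-bond partner;
* reference: small per-residue-type offsets discouraging composition drift.

Total energy of an assignment decomposes exactly as singles + pairs, and
every pair term is symmetric in its arguments.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .sidechains import is_acceptor, is_donor, vdw_radius
from .structio import BACKBONE_ATOMS, Structure

__all__ = ["AtomGroup", "EnergyModel", "extract_group", "residue_group"]

#: per-residue-type reference energies (arbitrary model units)
REFERENCE = {
    "ALA": 0.0, "GLY": 0.0, "SER": 0.1, "THR": 0.1, "CYS": 0.2,
    "VAL": 0.1, "LEU": 0.2, "ILE": 0.2, "MET": 0.3, "PRO": 0.3,
    "PHE": 0.4, "TYR": 0.4, "TRP": 0.6, "ASP": 0.2, "GLU": 0.3,
    "ASN": 0.2, "GLN": 0.3, "HIS": 0.3, "LYS": 0.4, "ARG": 0.5,
}


@dataclasses.dataclass
class AtomGroup:
    """Vectorized heavy-atom set with vdW radii and polar typing."""

    coords: np.ndarray  # (n, 3)
    radii: np.ndarray  # (n,)
    donor: np.ndarray  # (n,) bool
    acceptor: np.ndarray  # (n,) bool
    base: np.ndarray  # (n, 3) bonded-parent coordinate for the angular gate

    @property
    def n(self) -> int:
        return len(self.coords)

    @staticmethod
    def empty() -> "AtomGroup":
        z = np.zeros((0, 3))
        return AtomGroup(z, np.zeros(0), np.zeros(0, bool), np.zeros(0, bool), z)

    @staticmethod
    def concat(groups: list["AtomGroup"]) -> "AtomGroup":
        groups = [g for g in groups if g.n]
        if not groups:
            return AtomGroup.empty()
        return AtomGroup(
            np.vstack([g.coords for g in groups]),
            np.concatenate([g.radii for g in groups]),
            np.concatenate([g.donor for g in groups]),
            np.concatenate([g.acceptor for g in groups]),
            np.vstack([g.base for g in groups]),
        )


def _bases_for(atoms: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Bonded-parent proxy: nearest other heavy atom within 2.0 A."""
    names = [n for n in atoms if not n.startswith("H")]
    if len(names) == 1:
        return {names[0]: np.asarray(atoms[names[0]], float)}
    xyz = np.array([atoms[n] for n in names], float)
    d = np.sqrt(((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    nearest = d.argmin(axis=1)
    bases = {}
    for i, n in enumerate(names):
        bases[n] = xyz[nearest[i]] if d[i, nearest[i]] < 2.0 else xyz[i]
    return bases


def residue_group(
    res_name: str, atoms: dict[str, np.ndarray], include: str = "all"
) -> AtomGroup:
    """Build an AtomGroup from one residue's atoms.

    ``include``: "all" heavy atoms, "sidechain" (beyond N/CA/C/O), or
    "backbone".
    """
    names = [n for n in atoms if not n.startswith("H")]
    if include == "sidechain":
        names = [n for n in names if n not in BACKBONE_ATOMS]
    elif include == "backbone":
        names = [n for n in names if n in BACKBONE_ATOMS]
    if not names:
        return AtomGroup.empty()
    bases = _bases_for(atoms)
    return AtomGroup(
        np.array([atoms[n] for n in names], float),
        np.array([vdw_radius(n) for n in names]),
        np.array([is_donor(res_name, n) for n in names]),
        np.array([is_acceptor(res_name, n) for n in names]),
        np.array([bases[n] for n in names], float),
    )


def extract_group(
    s: Structure,
    skip: set[tuple[str, int]] | None = None,
    include: str = "all",
) -> AtomGroup:
    """AtomGroup over a structure's polymer residues, minus ``skip`` keys."""
    groups = []
    for ch in s.chains:
        for res in ch.polymer():
            if skip and (ch.id, res.number) in skip:
                continue
            groups.append(residue_group(res.name, res.atoms, include))
    return AtomGroup.concat(groups)


@dataclasses.dataclass
class EnergyModel:
    """Tunable weights of the four-term surrogate."""

    lj_eps: float = 0.15  # depth of the 8-4 well (model units)
    lj_cap: float = 20.0  # repulsion cap per pair
    hbond_strength: float = 2.0
    hbond_opt: float = 2.9  # A
    hbond_sigma: float = 0.3  # A
    hbond_max_dist: float = 3.5  # A
    burial_neighbors: int = 16  # heavy neighbours within burial_radius => buried
    burial_radius: float = 5.5  # A
    burial_penalty: float = 1.0
    reference: dict = dataclasses.field(default_factory=lambda: dict(REFERENCE))

    # -- pair terms --------------------------------------------------------

    def pair_energy(self, a: AtomGroup, b: AtomGroup) -> float:
        """Steric + H-bond energy between two atom groups (symmetric)."""
        if a.n == 0 or b.n == 0:
            return 0.0
        return float(self._pairwise_terms(a, b).sum())

    # -- vectorized candidate tables (used by the design stage) -----------

    def _cat(self, groups: list[AtomGroup]) -> tuple[AtomGroup, np.ndarray]:
        seg = np.concatenate(
            [np.full(g.n, i, dtype=int) for i, g in enumerate(groups)]
        ) if groups else np.zeros(0, int)
        return AtomGroup.concat(list(groups)), seg

    def _pairwise_terms(self, a: AtomGroup, b: AtomGroup) -> np.ndarray:
        """Full (na, nb) matrix of steric + H-bond pair energies."""
        # squared distances via the gemm identity; sqrt only where needed
        d2 = (
            (a.coords**2).sum(axis=1)[:, None]
            + (b.coords**2).sum(axis=1)[None, :]
            - 2.0 * (a.coords @ b.coords.T)
        )
        np.maximum(d2, 0.09, out=d2)
        s = a.radii[:, None] + b.radii[None, :]
        near = d2 < (s + 4.0) ** 2
        if not near.any():
            return np.zeros(d2.shape)
        d = np.sqrt(d2)
        ratio = np.where(near, s / d, 0.0)
        lj = self.lj_eps * (ratio**8 - 2.0 * ratio**4)
        out = np.where(near, np.minimum(lj, self.lj_cap), 0.0)

        def hb(don: AtomGroup, acc: AtomGroup, dmat: np.ndarray) -> np.ndarray:
            di = np.where(don.donor)[0]
            ai = np.where(acc.acceptor)[0]
            res = np.zeros_like(dmat)
            if len(di) == 0 or len(ai) == 0:
                return res
            sub = dmat[np.ix_(di, ai)]
            ok = (sub >= 2.4) & (sub <= self.hbond_max_dist)
            if not ok.any():
                return res
            v1 = don.base[di] - don.coords[di]
            v2 = acc.coords[ai][None, :, :] - don.coords[di][:, None, :]
            cos = (v1[:, None, :] * v2).sum(axis=2) / (
                np.linalg.norm(v1, axis=1)[:, None] * np.linalg.norm(v2, axis=2) + 1e-12
            )
            angular = np.clip(-cos, 0.0, 1.0)
            gauss = np.exp(-(((sub - self.hbond_opt) / self.hbond_sigma) ** 2))
            res[np.ix_(di, ai)] = -(self.hbond_strength * gauss * angular * ok)
            return res

        out = out + hb(a, b, d) + hb(b, a, d.T).T
        return out

    def pair_energy_table(
        self, groups_a: list[AtomGroup], groups_b: list[AtomGroup]
    ) -> np.ndarray:
        """(len(a), len(b)) table of pair energies between candidate groups."""
        cat_a, seg_a = self._cat(groups_a)
        cat_b, seg_b = self._cat(groups_b)
        tab = np.zeros((len(groups_a), len(groups_b)))
        if cat_a.n == 0 or cat_b.n == 0:
            return tab
        terms = self._pairwise_terms(cat_a, cat_b)
        np.add.at(tab, (seg_a[:, None], seg_b[None, :]), terms)
        return tab

    def single_energy_vector(
        self, groups: list[AtomGroup], env: AtomGroup
    ) -> np.ndarray:
        """Interaction + burial energy of each candidate group vs a fixed environment."""
        out = np.zeros(len(groups))
        if env.n == 0:
            return out
        cat, seg = self._cat(groups)
        if cat.n:
            terms = self._pairwise_terms(cat, env).sum(axis=1)
            np.add.at(out, seg, terms)
        # burial: neighbour-count proxy per polar atom
        from scipy.spatial import cKDTree

        tree = cKDTree(env.coords)
        polar = np.where(cat.donor | cat.acceptor)[0]
        if len(polar):
            counts = np.array(
                [len(tree.query_ball_point(cat.coords[i], self.burial_radius)) for i in polar]
            )
            for i, c in zip(polar, counts):
                if c >= self.burial_neighbors and not self.has_hbond_partner(
                    int(i), cat, env
                ):
                    out[seg[i]] += self.burial_penalty
        return out

    def has_hbond_partner(
        self, idx: int, group: AtomGroup, environment: AtomGroup
    ) -> bool:
        """Does polar atom ``idx`` of ``group`` H-bond to anything in ``environment``?"""
        xyz = group.coords[idx]
        d = np.linalg.norm(environment.coords - xyz, axis=1)
        for j in np.where((d >= 2.4) & (d <= self.hbond_max_dist))[0]:
            if group.donor[idx] and environment.acceptor[j]:
                v1 = group.base[idx] - xyz
                v2 = environment.coords[j] - xyz
            elif group.acceptor[idx] and environment.donor[j]:
                v1 = environment.base[j] - environment.coords[j]
                v2 = xyz - environment.coords[j]
            else:
                continue
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
            if cosang <= 0.0:  # angle >= 90 deg
                return True
        return False

    # -- single-body terms -------------------------------------------------

    def burial_term(self, group: AtomGroup, environment: AtomGroup) -> float:
        """Penalty for polar atoms of ``group`` buried in ``environment`` unsatisfied."""
        polar = np.where(group.donor | group.acceptor)[0]
        if len(polar) == 0 or environment.n == 0:
            return 0.0
        total = 0.0
        for idx in polar:
            d = np.linalg.norm(environment.coords - group.coords[idx], axis=1)
            if (d < self.burial_radius).sum() >= self.burial_neighbors and not self.has_hbond_partner(
                idx, group, environment
            ):
                total += self.burial_penalty
        return total

    def reference_energy(self, res_name: str) -> float:
        return self.reference.get(res_name, 0.0)

    # -- whole-structure scoring ------------------------------------------

    def structure_energy(self, s: Structure) -> float:
        """Total model energy: non-adjacent residue pairs + burial + reference.

        Pairs between sequence-adjacent residues of the same chain are
        skipped entirely (covalent neighbours would otherwise register as
        steric contacts).
        """
        entries: list[tuple[str, int, str, AtomGroup]] = []
        for ch in s.chains:
            for i, res in enumerate(ch.polymer()):
                entries.append((ch.id, i, res.name, residue_group(res.name, res.atoms)))
        e = 0.0
        for i in range(len(entries)):
            ci, ii, name_i, gi = entries[i]
            e += self.reference_energy(name_i)
            for j in range(i + 1, len(entries)):
                cj, ij, _name_j, gj = entries[j]
                if ci == cj and abs(ii - ij) == 1:
                    continue
                e += self.pair_energy(gi, gj)
        for i in range(len(entries)):
            ci, ii, _n, gi = entries[i]
            env = AtomGroup.concat(
                [g for k, (cj, ij, _nj, g) in enumerate(entries) if k != i]
            )
            e += self.burial_term(gi, env)
        return e
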