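"""Binding energy, shape complementarity, buried unsats and omega geometry."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bh3forge.energy import EnergyModel, residue_group
from bh3forge.filters import (
    FilterThresholds,
    binding_energy,
    buried_unsat_polar,
    evaluate_filters,
    omega_check,
    shape_complementarity,
)
from bh3forge.geometry import fibonacci_sphere
from bh3forge.sidechains import build_sidechain
from bh3forge.structio import Chain, Residue, Structure
from bh3forge.synthetic_data import HelixSpec, build_chain, build_helix



def wall(nx: int, ny: int, spacing: float, z: float, cid: str) -> Chain:
    """A flat one-residue chain of carbon atoms in the z plane."""
    atoms = {}
    k = 0
    for i in range(nx):
        for j in range(ny):
            atoms[f"C{k}"] = np.array([i * spacing, j * spacing, z])
            k += 1
    return Chain(cid, [Residue("ALA", 1, atoms)])


class TestBindingEnergy:
    def test_separated_partners_score_zero(self):
        a = build_helix(HelixSpec(length=6, sequence="AKELIA", chain_id="A"))
        b = build_helix(HelixSpec(length=6, sequence="ASELKA", chain_id="B"))
        for res in b.chains[0].residues:
            for n in res.atoms:
                res.atoms[n] = res.atoms[n] + np.array([100.0, 0.0, 0.0])
        cx = Structure([a.chains[0], b.chains[0]])
        assert binding_energy(cx) == pytest.approx(0.0, abs=1e-6)

    def test_ideal_intermolecular_hbond_is_favourable(self):
        # serine OG donor placed 2.9 A from a backbone-style O acceptor
        donor = Residue(
            "SER", 1,
            {
                "N": np.array([-1.46, 0.0, 0.0]),
                "CA": np.array([0.0, 0.0, 0.0]),
                "C": np.array([0.8, 1.3, 0.0]),
                "O": np.array([2.02, 1.3, 0.0]),
                "CB": np.array([0.5, -1.0, 1.0]),
                "OG": np.array([0.5, -1.5, 2.3]),
            },
        )
        og = donor.atoms["OG"]
        v = og - donor.atoms["CB"]
        v = v / np.linalg.norm(v)
        o_pos = og + 2.9 * v  # 2.9 A along the CB->OG axis: ideal donor geometry
        acceptor = Residue(
            "ALA", 1,
            {
                "N": o_pos + np.array([2.5, 2.5, 1.0]),
                "CA": o_pos + np.array([2.5, 1.2, 1.5]),
                "C": o_pos + np.array([1.2, 0.6, 1.2]),
                "O": o_pos,
            },
        )
        cx = Structure([Chain("A", [donor]), Chain("B", [acceptor])])
        assert binding_energy(cx) < -0.3

    def test_steric_clash_raises_binding_energy(self):
        base = build_helix(HelixSpec(length=5, sequence="ALAIA", chain_id="A"))
        probe = Residue("ALA", 1, {"N": np.zeros(3), "CA": np.array([1.46, 0, 0]), "C": np.array([2.0, 1.4, 0])})
        far = Structure([base.chains[0].copy(), Chain("B", [Residue("ALA", 1, {k: v + 50 for k, v in probe.atoms.items()})])])
        clashed = Structure([base.chains[0].copy(), Chain("B", [probe])])
        assert binding_energy(clashed) > binding_energy(far)

    def test_matches_interpartner_pair_sum_oracle(self):
        """No-repack value equals the brute-force sum over inter-partner residue pairs."""
        a = build_helix(HelixSpec(length=5, sequence="AKELA", chain_id="A"))
        b = build_helix(HelixSpec(length=5, sequence="ASQLA", chain_id="B"))
        for res in b.chains[0].residues:
            for n in res.atoms:
                res.atoms[n] = res.atoms[n] + np.array([0.0, 8.5, 1.0])
        cx = Structure([a.chains[0], b.chains[0]])
        em = EnergyModel()
        got = binding_energy(cx, em)
        brute = 0.0
        for ra in cx.chain("A").polymer():
            for rb in cx.chain("B").polymer():
                brute += em.pair_energy(
                    residue_group(ra.name, ra.atoms), residue_group(rb.name, rb.atoms)
                )
        # allow for complexation-induced burial penalties (integer multiples)
        assert got == pytest.approx(brute, abs=1e-6) or (got - brute) == pytest.approx(
            round(got - brute), abs=1e-6
        )

    def test_single_chain_input_rejected(self):
        helix = build_helix(HelixSpec(length=5))
        with pytest.raises(ValueError):
            binding_energy(helix)


class TestShapeComplementarity:
    def test_parallel_walls_score_high(self):
        cx = Structure([wall(8, 8, 1.5, 0.0, "A"), wall(8, 8, 1.5, 3.4, "B")])
        sc = shape_complementarity(cx, "A/B")
        assert sc >= 0.8

    def test_crossed_walls_score_lower_than_parallel(self):
        flat = Structure([wall(8, 8, 2.0, 0.0, "A"), wall(8, 8, 2.0, 3.4, "B")])
        sc_flat = shape_complementarity(flat, "A/B")
        # rotate the second wall 90 deg about x through its centre: a cross-gap
        crossed_wall = wall(8, 8, 2.0, 3.4, "B")
        centre = np.mean([v for v in crossed_wall.residues[0].atoms.values()], axis=0)
        R = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        for n, v in crossed_wall.residues[0].atoms.items():
            crossed_wall.residues[0].atoms[n] = R @ (v - centre) + centre + np.array([0, 0, 4.0])
        crossed = Structure([wall(8, 8, 2.0, 0.0, "A"), crossed_wall])
        sc_cross = shape_complementarity(crossed, "A/B")
        assert sc_cross < sc_flat

    def test_sc_bounded_and_deterministic(self, graft_complex):
        sc1 = shape_complementarity(graft_complex, "B/GH")
        sc2 = shape_complementarity(graft_complex, "B/GH")
        assert -1.0 <= sc1 <= 1.0
        assert sc1 == sc2

    def test_no_contact_raises(self):
        a = wall(4, 4, 2.0, 0.0, "A")
        b = wall(4, 4, 2.0, 100.0, "B")
        with pytest.raises(ValueError, match="no contact surface"):
            shape_complementarity(Structure([a, b]), "A/B")


def lysine_cage(with_acceptor: bool):
    """A lysine whose NZ is enclosed by a carbon cage from the other partner."""
    n = np.array([-1.46, 0.0, 0.0])
    ca = np.zeros(3)
    c = np.array([0.53, 1.43, 0.0])
    side = build_sidechain(n, ca, c, "LYS", (180.0, 180.0))
    lys = Residue("LYS", 1, {"N": n, "CA": ca, "C": c, "O": c + np.array([1.1, 0.5, 0.0]), **side})
    nz = side["NZ"]
    ce = side["CE"]
    cage_atoms = {}
    k = 0
    for u in fibonacci_sphere(80):
        p = nz + 4.0 * u
        if all(np.linalg.norm(p - x) > 3.2 for x in lys.atoms.values()):
            cage_atoms[f"C{k}"] = p
            k += 1
    if with_acceptor:
        # a carbonyl-style O 2.9 A from NZ, roughly opposite CE (good angle)
        direction = nz - ce
        direction /= np.linalg.norm(direction)
        cage_atoms["O"] = nz + 2.9 * direction
    cage = Residue("ALA", 1, cage_atoms)
    return Structure([Chain("A", [lys]), Chain("B", [cage])])


class TestBuriedUnsat:
    def test_isolated_chain_scores_zero(self):
        helix = build_helix(HelixSpec(length=6, sequence="AKAEASA"[:6]))
        assert buried_unsat_polar(helix) == 0

    def test_buried_lysine_nz_without_acceptor_counts_one(self):
        cx = lysine_cage(with_acceptor=False)
        assert buried_unsat_polar(cx, "A/B") == 1

    def test_wellplaced_acceptor_satisfies_the_donor(self):
        cx = lysine_cage(with_acceptor=True)
        assert buried_unsat_polar(cx, "A/B") == 0


class TestOmegaCheck:
    def test_ideal_helix_has_no_failures(self):
        helix = build_helix(HelixSpec(length=13))
        assert omega_check(helix) == []

    def test_distorted_omega_fails(self):
        chain = build_chain(
            [(-57.0, -47.0, 180.0), (-57.0, -47.0, 120.0), (-57.0, -47.0, 180.0), (-57.0, -47.0, 180.0)],
            "AAAA",
        )
        failures = omega_check(Structure([chain]))
        assert failures == [("A", 2)]

    def test_cis_proline_exempt_by_default(self):
        chain = build_chain(
            [(-57.0, -47.0, 180.0), (-57.0, -47.0, 2.0), (-75.0, 160.0, 180.0), (-57.0, -47.0, 180.0)],
            "AAPA",
        )
        s = Structure([chain])
        assert omega_check(s) == []
        assert omega_check(s, exempt_cis_proline=False) == [("A", 2)]

    def test_matches_independent_dihedral_recomputation(self):
        """Randomized chains: failure set equals a from-scratch dihedral oracle."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(3, 8))
            dihedrals = [
                (
                    float(rng.uniform(-150, -40)),
                    float(rng.uniform(-80, 160)),
                    float(rng.choice([180.0, 170.0, 120.0, 60.0, -160.0])),
                )
                for _ in range(n)
            ]
            s = Structure([build_chain(dihedrals, "A" * n, with_sidechains=False)])
            got = {num for _, num in omega_check(s, 150.0, exempt_cis_proline=False)}
            res = s.chains[0].residues
            oracle = set()
            for i in range(n - 1):
                b1 = res[i].atoms["C"] - res[i].atoms["CA"]
                b2 = res[i + 1].atoms["N"] - res[i].atoms["C"]
                b3 = res[i + 1].atoms["CA"] - res[i + 1].atoms["N"]
                n1 = np.cross(b1, b2)
                n2 = np.cross(b2, b3)
                cosw = n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2))
                omega = np.degrees(np.arccos(np.clip(cosw, -1, 1)))  # unsigned
                if omega < 150.0:
                    oracle.add(res[i].number)
            assert got == oracle

    def test_invariant_under_rigid_transform(self):
        chain = build_chain(
            [(-57.0, -47.0, 180.0), (-57.0, -47.0, 130.0), (-57.0, -47.0, 180.0), (-57.0, -47.0, 180.0)],
            "AAAA",
        )
        s = Structure([chain])
        moved = s.copy()
        R = Rotation.random(random_state=3).as_matrix()
        for _, _, _, xyz in list(moved.iter_atoms()):
            xyz[:] = R @ xyz + np.array([5.0, -3.0, 11.0])
        assert omega_check(s) == omega_check(moved)


class TestEvaluateFilters:
    def test_report_gates_and_thresholds(self, graft_complex):
        thr = FilterThresholds(ddg_max=1e6, sc_min=-1.0, unsat_max=1000)
        rep = evaluate_filters(graft_complex, "B/GH", thr)
        assert rep.overall
        impossible = FilterThresholds(sc_min=1.01)
        rep2 = evaluate_filters(graft_complex, "B/GH", impossible)
        assert not rep2.passes["sc"]

    def test_omega_cutoff_validation(self):
        with pytest.raises(ValueError):
            FilterThresholds(omega_cutoff=200.0)
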