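"""SASA gating, designable-position selection and Monte Carlo design."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from bh3forge.energy import EnergyModel, residue_group
from bh3forge.geometry import fibonacci_sphere
from bh3forge.interface_design import (
    DesignConfig,
    RotamerSet,
    assignment_energy,
    build_rotamer_set,
    design_protocol,
    mc_design,
    precompute_tables,
    select_designable,
)
from bh3forge.sasa import atom_sasa, sidechain_sasa
from bh3forge.structio import Structure
from bh3forge.synthetic_data import HelixSpec, build_helix


class TestSasa:
    def test_isolated_residue_is_fully_exposed(self):
        helix = build_helix(HelixSpec(length=4, sequence="AKAA"))
        values = sidechain_sasa(helix, probe=2.2)
        assert values[("A", 2)] > 30.0  # lysine side chain on a tiny peptide

    def test_caged_atom_has_near_zero_sasa(self):
        # one atom enclosed by a dense shell of neighbours
        shell = 3.0 * fibonacci_sphere(80)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.full(len(coords), 1.7)
        values = atom_sasa(coords, radii, probe=1.4, n_dots=960)
        assert values[0] < 1.0

    def test_dot_density_convergence(self):
        """Default dot density agrees with a 10x denser evaluation within 2%."""
        helix = build_helix(HelixSpec(length=5, sequence="AKLEA"))
        coarse = sidechain_sasa(helix, probe=1.4, n_dots=960)
        fine = sidechain_sasa(helix, probe=1.4, n_dots=10000)
        for key in coarse:
            assert coarse[key] == pytest.approx(fine[key], rel=0.02, abs=0.5)


class TestSelectDesignable:
    def test_distant_binder_selects_nothing(self, graft_complex):
        far = graft_complex.copy()
        for res in far.chain("B").polymer():
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + np.array([50.0, 0.0, 0.0])
        assert select_designable(far, "B", DesignConfig(), 8.0) == set()

    def test_shell_monotonicity(self, graft_complex):
        cfg = DesignConfig()
        s8 = select_designable(graft_complex, "B", cfg, 8.0)
        s12 = select_designable(graft_complex, "B", cfg, 12.0)
        assert s8 <= s12 and s8

    def test_matches_brute_force_double_loop(self, graft_complex):
        cfg = DesignConfig()
        got = select_designable(graft_complex, "B", cfg, 8.0)
        binder = graft_complex.chain("B")
        monomer_sasa = sidechain_sasa(
            Structure([binder.copy()]), probe=cfg.sasa_probe_radius, n_dots=cfg.sasa_dots
        )
        target = [
            xyz
            for ch in graft_complex.chains
            if ch.id != "B"
            for r in ch.polymer()
            for n, xyz in r.atoms.items()
        ]
        brute = set()
        for res in binder.polymer():
            if monomer_sasa[("B", res.number)] < cfg.surface_asa_min:
                continue
            if any(
                np.linalg.norm(a - b) <= 8.0
                for a in res.atoms.values()
                for b in target
            ):
                brute.add(res.number)
        assert got == brute

    def test_hotspots_never_designable(self, graft_complex, graft_solution, context_and_motif):
        _, motif = context_and_motif
        hotspots = tuple(graft_solution.window_start + k for k in motif.hotspot_indices)
        cfg = DesignConfig(hotspot_positions=hotspots)
        assert not (set(hotspots) & select_designable(graft_complex, "B", cfg, 12.0))


def tiny_design_fixture(seed: int, n_positions: int, max_cands: int):
    """Small binder helix near a fixed partner, with a trimmed rotamer set."""
    rng = np.random.default_rng(seed)
    binder = build_helix(HelixSpec(length=6, sequence="AAAAAA", chain_id="B"))
    partner = build_helix(HelixSpec(length=6, sequence="KELKEA", chain_id="T"))
    for res in partner.chains[0].residues:
        for n in res.atoms:
            res.atoms[n] = res.atoms[n] + np.array([0.0, 9.0 + rng.uniform(-0.5, 0.5), 0.0])
    cx = Structure([partner.chains[0], binder.chains[0]])
    positions = sorted(rng.choice(np.arange(2, 6), size=n_positions, replace=False).tolist())
    identities = ["ALA", "SER", "LEU", "GLU", "LYS", "PHE"]
    cands = {}
    for p in positions:
        k = int(rng.integers(2, max_cands + 1))
        pool = [("ALA", ())]
        for ident in rng.permutation(identities[1:]).tolist():
            for chi1 in (-60.0, 180.0):
                from bh3forge.sidechains import N_CHI

                n = N_CHI[ident]
                chis = (chi1,) + (180.0,) * max(n - 1, 0)
                pool.append((ident, chis[:n]))
        cands[p] = pool[:k]
    return cx, set(positions), RotamerSet(cands)


def exhaustive_minimum(cx, rotamers, energy, cfg):
    pos_list, singles, pairs, _ = precompute_tables(cx, "B", rotamers, energy)
    cands = [rotamers.candidates[p] for p in pos_list]
    best_e, best_state = np.inf, None
    for state in itertools.product(*(range(len(c)) for c in cands)):
        e = assignment_energy(np.array(state), singles, pairs)
        if e < best_e:
            best_e, best_state = e, state
    return best_e, {p: cands[i][best_state[i]] for i, p in enumerate(pos_list)}


class TestMCDesign:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
    def test_matches_exhaustive_enumeration(self, seed):
        """MC annealing finds the exact optimum on exhaustively solvable fixtures."""
        rng = np.random.default_rng(seed)
        cx, positions, rotamers = tiny_design_fixture(seed, int(rng.integers(1, 4)), 5)
        energy = EnergyModel()
        cfg = DesignConfig(seed=seed, mc_steps=2000)
        designed, rec = mc_design(cx, positions, rotamers, energy, cfg, "B")
        best_e, best_assign = exhaustive_minimum(cx, rotamers, energy, cfg)
        assert rec["final_energy"] == pytest.approx(best_e, abs=1e-9)
        for p, (ident, _chis) in best_assign.items():
            assert designed.chain("B").polymer()[p - 1].name == ident

    def test_single_position_returns_argmin(self):
        cx, _, rotamers = tiny_design_fixture(11, 1, 5)
        pos = set(rotamers.candidates)
        energy = EnergyModel()
        cfg = DesignConfig(seed=1, mc_steps=500)
        _, rec = mc_design(cx, pos, rotamers, energy, cfg, "B")
        best_e, _ = exhaustive_minimum(cx, rotamers, energy, cfg)
        assert rec["final_energy"] == pytest.approx(best_e, abs=1e-9)

    def test_zero_positions_is_identity(self, graft_complex):
        cfg = DesignConfig(seed=0)
        designed, rec = mc_design(graft_complex, set(), RotamerSet({1: [("ALA", ())]}), EnergyModel(), cfg, "B")
        assert rec["sequence"] == "".join(r.one_letter for r in graft_complex.chain("B").polymer())

    def test_deterministic_for_fixed_seed(self):
        cx, positions, rotamers = tiny_design_fixture(3, 3, 4)
        cfg = DesignConfig(seed=9, mc_steps=1500)
        _, r1 = mc_design(cx, positions, rotamers, EnergyModel(), cfg, "B")
        _, r2 = mc_design(cx, positions, rotamers, EnergyModel(), cfg, "B")
        assert r1["sequence"] == r2["sequence"]
        assert r1["trace"] == r2["trace"]

    def test_final_energy_never_exceeds_initial(self):
        for seed in range(5):
            cx, positions, rotamers = tiny_design_fixture(20 + seed, 2, 4)
            cfg = DesignConfig(seed=seed, mc_steps=800)
            _, rec = mc_design(cx, positions, rotamers, EnergyModel(), cfg, "B")
            assert rec["final_energy"] <= rec["initial_energy"] + 1e-9


class TestEnergyModel:
    def test_pair_energy_symmetry(self):
        rng = np.random.default_rng(0)
        helix = build_helix(HelixSpec(length=6, sequence="KELSIA"))
        res = helix.chains[0].residues
        em = EnergyModel()
        for i, j in itertools.combinations(range(6), 2):
            gi = residue_group(res[i].name, res[i].atoms)
            gj = residue_group(res[j].name, res[j].atoms)
            assert em.pair_energy(gi, gj) == pytest.approx(em.pair_energy(gj, gi), abs=1e-9)

    def test_total_decomposes_into_singles_plus_pairs(self):
        cx, positions, rotamers = tiny_design_fixture(5, 3, 4)
        em = EnergyModel()
        pos_list, singles, pairs, _ = precompute_tables(cx, "B", rotamers, em)
        rng = np.random.default_rng(1)
        cands = [rotamers.candidates[p] for p in pos_list]
        state = np.array([rng.integers(len(c)) for c in cands])
        total = assignment_energy(state, singles, pairs)
        manual = sum(singles[i][state[i]] for i in range(len(state)))
        manual += sum(tab[state[i], state[j]] for (i, j), tab in pairs.items())
        assert total == pytest.approx(manual, abs=1e-12)

    def test_longer_schedule_not_worse_on_average(self):
        """Mean best-energy over a seed family: long schedules >= short ones."""
        short, long = [], []
        for seed in range(10):
            cx, positions, rotamers = tiny_design_fixture(40 + seed, 3, 6)
            em = EnergyModel()
            for steps, sink in ((100, short), (3000, long)):
                cfg = DesignConfig(seed=seed, mc_steps=steps)
                _, rec = mc_design(cx, positions, rotamers, em, cfg, "B")
                sink.append(rec["final_energy"])
        assert np.mean(long) <= np.mean(short) + 1e-9


class TestDesignProtocol:
    def test_protocol_monotone_and_constrained(self, graft_complex, graft_solution, context_and_motif):
        _, motif = context_and_motif
        hotspots = tuple(graft_solution.window_start + k for k in motif.hotspot_indices)
        cfg = DesignConfig(seed=3, mc_steps=1200, hotspot_positions=hotspots, shell_distances=(6.0, 9.0))
        designed, rec = design_protocol(graft_complex, cfg, EnergyModel())
        # each stage's best state is at least as good as its own start
        for st in rec["stages"]:
            assert st["final_energy"] <= st["initial_energy"] + 1e-9
        # hotspot identities untouched
        seq = rec["sequence"]
        hs_ids = dict(zip(motif.hotspot_indices, motif.hotspot_identities))
        for k, aa in hs_ids.items():
            assert seq[graft_solution.window_start + k - 1] == aa
        # disallowed types never introduced at designed positions
        native = "".join(
            r.one_letter for r in graft_complex.chain("B").polymer()
        )
        for a, b in zip(native, seq):
            if a != b:
                assert b not in "PCWG"

    def test_protocol_deterministic(self, graft_complex, graft_solution, context_and_motif):
        _, motif = context_and_motif
        hotspots = tuple(graft_solution.window_start + k for k in motif.hotspot_indices)
        cfg = DesignConfig(seed=5, mc_steps=600, hotspot_positions=hotspots, shell_distances=(6.0, 9.0))
        _, r1 = design_protocol(graft_complex, cfg, EnergyModel())
        _, r2 = design_protocol(graft_complex, cfg, EnergyModel())
        assert r1["sequence"] == r2["sequence"]
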