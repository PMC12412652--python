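"""Variant counting, enrichment, dual selection and library design."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bh3forge.maturation import (
    CombinatorialLibrary,
    PoolCounts,
    best_degenerate_codon,
    count_variants,
    design_combinatorial_library,
    dual_select,
    enrichment,
    expand_degenerate_codon,
    library_diversity,
)
from bh3forge.structio import ProteinSequence
from bh3forge.synthetic_data import reads_from_counts, simulate_ssm_pools

PARENT = ProteinSequence("parent", "MKTAYIAKQRQISFVK")


class TestCountVariants:
    def test_parent_only_reads_fill_wildtype_bin(self):
        pool = count_variants([PARENT.residues] * 5, PARENT)
        assert pool.wildtype == 5 and pool.counts == {} and pool.discarded == 0

    def test_single_substitution_tallied_under_its_key(self):
        read = PARENT.residues[:6] + "K" + PARENT.residues[7:]
        pool = count_variants([read], PARENT)
        assert pool.counts == {(7, "A", "K"): 1}

    def test_multimutant_stop_and_length_reads_discarded(self):
        double = "W" + PARENT.residues[1:-1] + "W"
        stop = PARENT.residues[:3] + "*" + PARENT.residues[4:]
        short = PARENT.residues[:-1]
        pool = count_variants([double, stop, short, PARENT.residues], PARENT)
        assert pool.discarded == 3 and pool.wildtype == 1

    def test_simulated_pool_counts_match_generator_tallies(self):
        naive, _aff, _spec, _truth = simulate_ssm_pools(PARENT, {}, depth=2000, seed=11)
        reads = reads_from_counts(PARENT, naive)
        recounted = count_variants(reads, PARENT)
        assert recounted.counts == naive.counts
        assert recounted.wildtype == naive.wildtype


def pool(condition: str, counts: dict, wt: int = 0) -> PoolCounts:
    return PoolCounts("p", condition, counts, wildtype=wt)


class TestEnrichment:
    def test_identical_pools_score_zero_everywhere(self):
        counts = {(1, "M", "A"): 50, (2, "K", "R"): 70}
        res = enrichment(pool("naive", counts), pool("affinity_sort", dict(counts)))
        assert all(abs(e) < 1e-12 for e in res.scores.values())
        assert res.enriched == set()

    def test_doubled_frequency_approaches_log2_of_two(self):
        # one mutation doubles in relative frequency; pseudocount -> 0 limit
        naive = pool("naive", {(1, "M", "A"): 1000, (2, "K", "R"): 1000})
        sel = pool("affinity_sort", {(1, "M", "A"): 2000, (2, "K", "R"): 1000})
        res = enrichment(naive, sel, pseudocount=1e-9)
        expected = np.log2((2000 / 3000) / (1000 / 2000))
        assert res.scores[(1, "M", "A")] == pytest.approx(expected, abs=1e-6)

    def test_swapping_pools_negates_scores(self):
        rng = np.random.default_rng(0)
        muts = [(i, "A", aa) for i, aa in zip(range(1, 9), "CDEFGHIK")]
        a = pool("naive", {m: int(rng.integers(10, 500)) for m in muts})
        b = pool("affinity_sort", {m: int(rng.integers(10, 500)) for m in muts})
        fwd = enrichment(a, b).scores
        rev = enrichment(
            PoolCounts("p", "naive", b.counts), PoolCounts("p", "affinity_sort", a.counts)
        ).scores
        for m in muts:
            assert fwd[m] == pytest.approx(-rev[m], abs=1e-12)

    def test_planted_effects_rank_top(self):
        rng = np.random.default_rng(3)
        parent = ProteinSequence("p", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVY"), 20)))
        planted = {}
        while len(planted) < 5:
            pos = int(rng.integers(1, 21))
            to = str(rng.choice([a for a in "ACDEFGHIKLMNPQRSTVWY" if a != parent[pos - 1]]))
            planted[(pos, parent[pos - 1], to)] = (4.0, 0.0)
        naive, aff, _spec, _ = simulate_ssm_pools(parent, planted, depth=100_000, seed=3)
        res = enrichment(naive, aff)
        top5 = sorted(res.scores, key=res.scores.get, reverse=True)[:5]
        assert set(top5) == set(planted)

    def test_zero_total_pool_rejected(self):
        with pytest.raises(ValueError, match="zero-total"):
            enrichment(pool("naive", {(1, "M", "A"): 5}), pool("affinity_sort", {(2, "K", "R"): 1}))


class TestDualSelect:
    def _result(self, enriched):
        from bh3forge.maturation import EnrichmentResult

        return EnrichmentResult({m: 2.0 for m in enriched}, 0.5, 1.0, 10, set(enriched))

    def test_disjoint_sets_select_nothing(self):
        a = self._result({(1, "A", "K")})
        b = self._result({(2, "S", "R")})
        assert dual_select(a, b) == set()

    def test_equal_sets_select_all(self):
        muts = {(1, "A", "K"), (3, "L", "I")}
        assert dual_select(self._result(muts), self._result(muts)) == muts

    def test_intersection_and_subset_property(self):
        a = self._result({(1, "A", "K"), (2, "S", "R"), (5, "V", "L")})
        b = self._result({(2, "S", "R"), (5, "V", "L"), (9, "T", "N")})
        got = dual_select(a, b)
        assert got == {(2, "S", "R"), (5, "V", "L")}
        assert got <= a.enriched and got <= b.enriched

    def test_wildtype_identities_never_selected(self):
        wt = (4, "A", "A")
        a = self._result({wt, (1, "A", "K")})
        assert wt not in dual_select(a, a)


class TestDegenerateCodons:
    def test_all_twenty_requires_nnk(self):
        codon, aas = best_degenerate_codon(set("ACDEFGHIKLMNPQRSTVWY"))
        assert codon == "NNK"
        assert len(expand_degenerate_codon(codon)) == 32
        assert aas == set("ACDEFGHIKLMNPQRSTVWY")

    def test_single_aa_gets_unique_codon(self):
        codon, aas = best_degenerate_codon({"M"})
        assert codon == "ATG" and aas == {"M"}

    def test_every_expansion_translates_into_declared_set(self):
        from Bio.Data.CodonTable import standard_dna_table

        rng = np.random.default_rng(5)
        for _ in range(10):
            req = set(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=rng.integers(1, 6), replace=False))
            codon, aas = best_degenerate_codon(req)
            translated = {
                standard_dna_table.forward_table.get(c)
                for c in expand_degenerate_codon(codon)
                if c not in standard_dna_table.stop_codons
            }
            assert translated == aas and req <= aas


class TestLibraryDesign:
    def test_empty_selection_gives_parent_only(self):
        lib = design_combinatorial_library(PARENT, set())
        assert library_diversity(lib) == (1, 1)

    def test_two_nnk_positions(self):
        sel = {
            (3, "T", aa): 1.0
            for aa in "ACDEFGHIKLMNPQRSVWY"
        }
        sel.update({(5, "Y", aa): 1.0 for aa in "ACDEFGHIKLMNPQRSTVW"})
        lib = design_combinatorial_library(PARENT, sel)
        dna, protein = library_diversity(lib)
        assert dna == 32 * 32 and protein == 20 * 20

    def test_cap_pruning_reports_drops_and_respects_cap(self):
        parent = ProteinSequence("p", "A" * 20)
        sel = {}
        rng = np.random.default_rng(1)
        for pos in range(1, 21):
            for aa in "KRDE":  # with parent A: 5 AAs per position
                sel[(pos, "A", aa)] = float(rng.uniform(0.5, 3.0))
        lib = design_combinatorial_library(parent, sel, cap=4e7)
        assert lib.protein_diversity <= 4e7
        assert lib.dropped, "pruning must report the dropped mutations"
        # drops are lowest-enrichment first
        drop_scores = [s for _, s in lib.dropped]
        survivors = [s for m, s in sel.items() if (m, s) not in lib.dropped]
        assert max(drop_scores) <= min(survivors) + 1e-12

    def test_every_surviving_mutation_is_encodable(self):
        parent = ProteinSequence("p", "A" * 10)
        sel = {(pos, "A", aa): float(pos) for pos in range(1, 11) for aa in "KRDEQ"}
        lib = design_combinatorial_library(parent, sel, cap=1e6)
        dropped = {m for m, _ in lib.dropped}
        for m in sel:
            if m not in dropped:
                assert lib.encodes(m)
        # parent residue always encoded at every varied position
        for pos, (codon, aas) in lib.positions.items():
            assert parent[pos - 1] in aas

    def test_degenerate_cap_one_gives_parent_only(self):
        sel = {(1, "M", "K"): 2.0, (2, "K", "R"): 1.0}
        lib = design_combinatorial_library(PARENT, sel, cap=1)
        assert lib.protein_diversity == 1
        assert len(lib.dropped) == 2

    def test_mismatched_parent_identity_rejected(self):
        with pytest.raises(ValueError, match="does not match parent"):
            design_combinatorial_library(PARENT, {(1, "W", "K")})

    def test_diversity_matches_enumeration_on_small_library(self):
        sel = {(2, "K", "R"): 1.0, (4, "A", "G"): 1.0, (6, "I", "L"): 1.0}
        lib = design_combinatorial_library(PARENT, sel)
        dna, protein = library_diversity(lib)
        combos = set()
        from Bio.Data.CodonTable import standard_dna_table

        per_pos_aas = [sorted(aas) for _, (codon, aas) in sorted(lib.positions.items())]
        for combo in itertools.product(*per_pos_aas):
            combos.add(combo)
        assert len(combos) == protein
        dna_combos = 1
        for _, (codon, _aas) in sorted(lib.positions.items()):
            dna_combos *= len(expand_degenerate_codon(codon))
        assert dna_combos == dna


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=10, deadline=None)
def test_dual_select_monotone_in_thresholds(seed):
    """Raising either enrichment threshold never grows the dual selection."""
    rng = np.random.default_rng(seed)
    muts = [(i, "A", aa) for i, aa in zip(range(1, 13), "CDEFGHIKLMNQ")]
    naive = pool("naive", {m: int(rng.integers(20, 300)) for m in muts})
    affc = pool("affinity_sort", {m: int(rng.integers(1, 600)) for m in muts})
    spec = pool("specificity_sort", {m: int(rng.integers(1, 600)) for m in muts})
    prev = None
    for thr in (0.2, 0.6, 1.2):
        sel = dual_select(
            enrichment(naive, affc, threshold=thr),
            enrichment(naive, spec, threshold=thr),
        )
        if prev is not None:
            assert sel <= prev
        prev = sel
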