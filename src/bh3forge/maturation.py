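"""Directed-evolution analytics for site-saturation mutagenesis screens.

Covers the computational side of yeast-display affinity/specificity
maturation: tallying single-substitution variants from sequenced pools,
log2 frequency-ratio enrichment of sorted vs naive pools, the
dual-criterion rule (a mutation enters combinatorial libraries only if it
enriches independently under BOTH the affinity sort and the specificity
sort), and degenerate-codon combinatorial library design under a protein
diversity cap (default < 4e7 variants).

Mutations are keyed ``(position, from_aa, to_aa)`` with 1-based positions on
the parent designed domain.
"""

from __future__ import annotations

import dataclasses
import functools
import itertools
import math
from typing import Iterable, Mapping

from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values

from .structio import ProteinSequence

__all__ = [
    "Mutation",
    "PoolCounts",
    "EnrichmentResult",
    "CombinatorialLibrary",
    "count_variants",
    "enrichment",
    "dual_select",
    "design_combinatorial_library",
    "library_diversity",
    "best_degenerate_codon",
    "expand_degenerate_codon",
]

Mutation = tuple[int, str, str]  # (1-based position, from AA, to AA)

_CONDITIONS = ("naive", "affinity_sort", "specificity_sort")


@dataclasses.dataclass
class PoolCounts:
    """Variant read counts for one sequenced pool."""

    pool_id: str
    condition: str
    counts: dict[Mutation, int]
    wildtype: int = 0
    discarded: int = 0

    def __post_init__(self) -> None:
        if self.condition not in _CONDITIONS:
            raise ValueError(f"condition must be one of {_CONDITIONS}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.wildtype + self.discarded


@dataclasses.dataclass
class EnrichmentResult:
    """Per-mutation log2 enrichment of a sorted pool over the naive pool."""

    scores: dict[Mutation, float]
    pseudocount: float
    threshold: float
    min_naive_coverage: int
    enriched: set[Mutation]
    condition: str = ""


def count_variants(
    reads: Iterable[str], parent: ProteinSequence
) -> PoolCounts:
    """Tally single-substitution variants among amino-acid reads.

    Reads equal to the parent count as wild type; reads differing at exactly
    one position are tallied under that ``(position, from, to)`` key. Reads
    of the wrong length, with stops (``*``), or with >= 2 substitutions are
    discarded and counted (SSM pools are single-substitution by
    construction; anything else is an artifact).
    """
    counts: dict[Mutation, int] = {}
    wt = 0
    discarded = 0
    pseq = parent.residues
    for read in reads:
        read = read.upper()
        if len(read) != len(pseq) or "*" in read:
            discarded += 1
            continue
        diffs = [(i, a, b) for i, (a, b) in enumerate(zip(pseq, read), start=1) if a != b]
        if not diffs:
            wt += 1
        elif len(diffs) == 1:
            i, a, b = diffs[0]
            key = (i, a, b)
            counts[key] = counts.get(key, 0) + 1
        else:
            discarded += 1
    return PoolCounts("pool", "naive", counts, wildtype=wt, discarded=discarded)


def enrichment(
    naive: PoolCounts,
    selected: PoolCounts,
    pseudocount: float = 0.5,
    threshold: float = 1.0,
    min_naive_coverage: int = 10,
) -> EnrichmentResult:
    """log2 frequency-ratio enrichment with additive pseudocount.

    For each mutation m tracked in the naive pool::

        e_m = log2( (c_sel(m)+p)/(T_sel+p*M) / ((c_naive(m)+p)/(T_naive+p*M)) )

    where the T are mutation-read totals and M the number of tracked
    mutations. m is flagged enriched iff ``e_m > threshold`` and its naive
    count meets the coverage floor.
    """
    tracked = sorted(naive.counts)
    if not tracked:
        raise ValueError("naive pool tracks no mutations")
    M = len(tracked)
    t_naive = sum(naive.counts.values())
    t_sel = sum(selected.counts.get(m, 0) for m in tracked)
    if t_naive == 0 or t_sel == 0:
        raise ValueError("zero-total pool")
    p = pseudocount
    scores: dict[Mutation, float] = {}
    enriched: set[Mutation] = set()
    for m in tracked:
        f_sel = (selected.counts.get(m, 0) + p) / (t_sel + p * M)
        f_naive = (naive.counts[m] + p) / (t_naive + p * M)
        e = math.log2(f_sel / f_naive)
        scores[m] = e
        if e > threshold and naive.counts[m] >= min_naive_coverage:
            enriched.add(m)
    return EnrichmentResult(
        scores, p, threshold, min_naive_coverage, enriched, selected.condition
    )


def dual_select(aff: EnrichmentResult, spec: EnrichmentResult) -> set[Mutation]:
    """Mutations independently enriched under BOTH sort conditions.

    The intersection rule: only mutations that improve affinity and
    specificity in independent sorts are carried into combinatorial
    libraries. Wild-type identities (to == from) are never selected.
    """
    return {
        m for m in aff.enriched & spec.enriched if m[1] != m[2]
    }


# -- degenerate codons -----------------------------------------------------

_CODON_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)
_IUPAC = {k: v for k, v in ambiguous_dna_values.items() if k != "U"}
# sorted IUPAC letters for deterministic tie-breaking
_IUPAC_LETTERS = sorted(_IUPAC)


def expand_degenerate_codon(codon: str) -> list[str]:
    """All concrete DNA codons matched by a 3-letter IUPAC degenerate codon."""
    if len(codon) != 3 or any(b not in _IUPAC for b in codon):
        raise ValueError(f"bad degenerate codon {codon!r}")
    return ["".join(bases) for bases in itertools.product(*(_IUPAC[b] for b in codon))]


@functools.lru_cache(maxsize=None)
def _codon_aas(codon: str) -> tuple[frozenset[str], int, int]:
    """(encoded AA set, DNA multiplicity, stop-codon count) for a degenerate codon."""
    expanded = expand_degenerate_codon(codon)
    aas = set()
    stops = 0
    for c in expanded:
        if c in _STOPS:
            stops += 1
        else:
            aas.add(_CODON_TABLE[c])
    return frozenset(aas), len(expanded), stops


def best_degenerate_codon(
    required: set[str] | frozenset[str], allow_stops: bool = True
) -> tuple[str, set[str]]:
    """Minimal-multiplicity IUPAC codon whose AA set covers ``required``.

    Ties broken by fewest extra amino acids, then fewest stop codons, then
    lexicographic codon. With ``allow_stops=False`` codons encoding any stop
    are rejected outright (strict no-stop mode).
    """
    if not required or not required <= set("ACDEFGHIKLMNPQRSTVWY"):
        raise ValueError(f"bad required AA set {required!r}")
    codon, aas = _best_degenerate_codon_cached(frozenset(required), allow_stops)
    return codon, set(aas)


@functools.lru_cache(maxsize=None)
def _best_degenerate_codon_cached(
    required: frozenset[str], allow_stops: bool
) -> tuple[str, frozenset[str]]:
    best = None
    for codon in itertools.product(_IUPAC_LETTERS, repeat=3):
        text = "".join(codon)
        aas, mult, stops = _codon_aas(text)
        if not required <= aas:
            continue
        if stops and not allow_stops:
            continue
        key = (mult, len(aas - required), stops, text)
        if best is None or key < best[0]:
            best = (key, text, aas)
    if best is None:  # unreachable for <= 20-AA sets with N available
        raise RuntimeError(f"no degenerate codon covers {required}")
    return best[1], best[2]


@dataclasses.dataclass
class CombinatorialLibrary:
    """Degenerate-codon library: per-position codon + encoded AA sets."""

    parent: ProteinSequence
    positions: dict[int, tuple[str, frozenset[str]]]  # pos -> (codon, AA set)
    diversity_cap: float = 4e7
    dropped: list[tuple[Mutation, float]] = dataclasses.field(default_factory=list)

    @property
    def dna_diversity(self) -> int:
        prod = 1
        for codon, _ in self.positions.values():
            prod *= len(expand_degenerate_codon(codon))
        return prod

    @property
    def protein_diversity(self) -> int:
        prod = 1
        for _, aas in self.positions.values():
            prod *= len(aas)
        return prod

    def encodes(self, m: Mutation) -> bool:
        pos, _, to = m
        if pos not in self.positions:
            return False
        return to in self.positions[pos][1]


def design_combinatorial_library(
    parent: ProteinSequence,
    selected: Mapping[Mutation, float] | set[Mutation],
    cap: float = 4e7,
    allow_stops: bool = True,
) -> CombinatorialLibrary:
    """Build a degenerate-codon combinatorial library from selected mutations.

    Each position with selected substitutions gets the minimal-multiplicity
    degenerate codon covering {parent AA} union {selected AAs}. If the
    protein diversity (product of encoded AA-set sizes, stops excluded)
    exceeds the cap, the lowest-enrichment mutations are greedily dropped
    until the library fits, and the drops are reported on the result.

    ``selected`` may be a mapping mutation -> enrichment score (used for the
    pruning order) or a bare set (pruning order then falls back to position/
    alphabetic order, lowest priority dropped first deterministically).
    """
    if isinstance(selected, Mapping):
        scored = dict(selected)
    else:
        scored = {m: 0.0 for m in selected}
    for pos, frm, to in scored:
        if not (1 <= pos <= len(parent)):
            raise ValueError(f"mutation position {pos} outside parent (1..{len(parent)})")
        if parent[pos - 1] != frm:
            raise ValueError(f"mutation {(pos, frm, to)} does not match parent {parent[pos - 1]}{pos}")

    def build(muts: dict[Mutation, float]) -> dict[int, tuple[str, frozenset[str]]]:
        by_pos: dict[int, set[str]] = {}
        for (pos, _frm, to) in muts:
            by_pos.setdefault(pos, set()).add(to)
        out = {}
        for pos, tos in sorted(by_pos.items()):
            required = tos | {parent[pos - 1]}
            codon, aas = best_degenerate_codon(required, allow_stops=allow_stops)
            out[pos] = (codon, frozenset(aas))
        return out

    surviving = dict(scored)
    dropped: list[tuple[Mutation, float]] = []
    positions = build(surviving)
    lib = CombinatorialLibrary(parent, positions, cap, dropped)
    # greedy pruning: drop ascending by enrichment score until under the cap
    order = sorted(surviving, key=lambda m: (scored[m], m))
    while lib.protein_diversity > cap and surviving:
        victim = order.pop(0)
        dropped.append((victim, scored[victim]))
        del surviving[victim]
        lib = CombinatorialLibrary(parent, build(surviving), cap, dropped)
    return lib


def library_diversity(lib: CombinatorialLibrary) -> tuple[int, int]:
    """(DNA diversity, protein diversity) as exact integer products."""
    return lib.dna_diversity, lib.protein_diversity
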