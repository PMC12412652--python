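"""Synthetic-data generators with known ground truth for every pipeline stage.

Every generator is deterministic per seed and hands back its ground truth
alongside the data, so grafting, design, filtering, maturation, kinetics and
mechanism stages are all testable without any external downloads.

The structural generators build ideal-geometry helices (NeRF chain
construction from backbone dihedrals) and poly-alanine groove complexes with
a few large hydrophobics lining the cleft: enough chemistry for the energy
terms and filters to discriminate poses without pretending to be real BAK.

``lineage_sequences`` provides SYNTHETIC stand-in binder lineages whose
Hamming structure matches the published mutation counts between design-stage
precursors and evolved variants; the real deposited sequences are not
shipped with the package.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import place_atom
from .maturation import Mutation, PoolCounts
from .pore_model import MechanismParams, simulate_dose_response
from .sidechains import build_sidechain
from .structio import (
    Chain,
    ONE_TO_THREE,
    ProteinSequence,
    Residue,
    Structure,
)

__all__ = [
    "HelixSpec",
    "ToyComplexSpec",
    "build_helix",
    "build_chain",
    "build_scaffold_bundle",
    "build_toy_complex",
    "lineage_sequences",
    "simulate_ssm_pools",
    "reads_from_counts",
    "simulate_liposome_traces",
]

# ideal backbone internal coordinates
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


@dataclasses.dataclass
class HelixSpec:
    """Ideal alpha-helix: length, backbone dihedrals, sequence, placement."""

    length: int = 13
    phi: float = -57.0
    psi: float = -47.0
    omega: float = 180.0
    sequence: str | None = None  # default poly-alanine
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if self.length < 4:
            raise ValueError("helix length must be >= 4")
        if not (-180.0 < self.phi < 0.0 and -120.0 < self.psi < 60.0):
            raise ValueError("dihedrals outside the helical region")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length mismatch")


def build_chain(
    dihedrals: list[tuple[float, float, float]],
    sequence: str,
    chain_id: str = "A",
    start_number: int = 1,
    with_sidechains: bool = True,
) -> Chain:
    """Build a polymer chain from per-residue (phi, psi, omega) dihedrals.

    phi of residue 1 and psi/omega of the last residue are placement
    conventions only. Side chains use the coarse ideal-geometry builder with
    a helical-ish chi1 of -60 degrees.
    """
    n = len(dihedrals)
    if len(sequence) != n:
        raise ValueError("sequence/dihedral length mismatch")
    N = [np.zeros(3)]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    dummy = np.array([0.0, 1.0, 0.0])
    C = [place_atom(dummy, N[0], CA[0], _B_CA_C, _A_N_CA_C, 30.0)]
    for i in range(n - 1):
        _, psi_i, omega_i = dihedrals[i]
        phi_next = dihedrals[i + 1][0]
        N.append(place_atom(N[i], CA[i], C[i], _B_C_N, _A_CA_C_N, psi_i))
        CA.append(place_atom(CA[i], C[i], N[i + 1], _B_N_CA, _A_C_N_CA, omega_i))
        C.append(place_atom(C[i], N[i + 1], CA[i + 1], _B_CA_C, _A_N_CA_C, phi_next))
    residues = []
    for i in range(n):
        psi_i = dihedrals[i][1]
        O = place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi_i + 180.0)
        atoms = {"N": N[i], "CA": CA[i], "C": C[i], "O": O}
        name = ONE_TO_THREE[sequence[i]]
        if with_sidechains:
            atoms.update(build_sidechain(N[i], CA[i], C[i], name, (-60.0, 180.0)))
        residues.append(Residue(name, start_number + i, atoms))
    return Chain(chain_id, residues)


def build_helix(spec: HelixSpec) -> Structure:
    """Ideal helix as a one-chain Structure; measured dihedrals match the spec."""
    seq = spec.sequence or "A" * spec.length
    dihedrals = [(spec.phi, spec.psi, spec.omega)] * spec.length
    chain = build_chain(dihedrals, seq, spec.chain_id)
    s = Structure([chain], {"entry_id": "HLX"})
    if spec.rotation is not None or spec.translation is not None:
        R = spec.rotation if spec.rotation is not None else np.eye(3)
        t = spec.translation if spec.translation is not None else np.zeros(3)
        _transform(s, R, t)
    return s


def _transform(s: Structure, R: np.ndarray, t: np.ndarray) -> None:
    for _, _, name, xyz in list(s.iter_atoms()):
        xyz[:] = R @ xyz + t


def _helix_axis(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    ca = np.array([r.atoms["CA"] for r in chain.residues])
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    return centroid, vt[0]


def build_scaffold_bundle(
    motif_length: int = 13,
    helix_lengths: tuple[int, int, int] = (14, 16, 14),
    loop_length: int = 4,
    sequence_seed: int = 0,
    chain_id: str = "S",
) -> Structure:
    """Three-helix "bundle" scaffold as one chain: helix-loop-helix-loop-helix.

    The middle helix is built on ideal helical dihedrals, so every
    motif_length window inside it is graft-compatible with an ideal helical
    motif by construction. Sequence is a deterministic mix of small/large
    hydrophobics and polars drawn from ``sequence_seed``.
    """
    rng = np.random.default_rng(sequence_seed)
    alphabet = list("ADEFIKLNQRSTVY")
    dihedrals: list[tuple[float, float, float]] = []
    segments = []
    for h, hl in enumerate(helix_lengths):
        segments.append([(-57.0, -47.0, 180.0)] * hl)
        if h < len(helix_lengths) - 1:
            segments.append([(-75.0, 145.0, 180.0)] * loop_length)
    for seg in segments:
        dihedrals.extend(seg)
    n = len(dihedrals)
    seq = "".join(rng.choice(alphabet) for _ in range(n))
    chain = build_chain(dihedrals, seq, chain_id)
    if helix_lengths[1] < motif_length:
        raise ValueError("middle helix shorter than the motif")
    return Structure([chain], {"entry_id": "SCAF"})


@dataclasses.dataclass
class ToyComplexSpec:
    """Toy groove complex: two flanking helices forming a cleft + docked motif."""

    motif_length: int = 13
    motif_sequence: str = "IAAALAAIGDAAA"  # canonical hotspots at 1,5,8,9,10 (I,L,I,G,D)
    groove_length: int = 16
    groove_separation: float = 10.5  # between groove helix axes (A)
    motif_offset: float = 8.6  # motif axis distance from the groove plane (A)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.motif_sequence) != self.motif_length:
            raise ValueError("motif sequence length mismatch")


def build_toy_complex(spec: ToyComplexSpec) -> Structure:
    """Three-chain toy complex: groove helices G/H (the target) + motif chain P.

    The groove helices run antiparallel in the y = 0 plane with a few
    leucines/isoleucines pointing into the cleft; the motif helix lies above
    the gap between them. Deterministic per seed (the seed perturbs the
    groove sequences slightly). The construction guarantees inter-chain
    heavy-atom contacts below 5 A.
    """
    rng = np.random.default_rng(spec.seed)

    def groove_seq() -> str:
        base = list("A" * spec.groove_length)
        for i in range(2, spec.groove_length - 2, 3):
            base[i] = "L" if rng.random() < 0.7 else "I"
        return "".join(base)

    g1 = build_chain([(-57.0, -47.0, 180.0)] * spec.groove_length, groove_seq(), "G")
    g2 = build_chain([(-57.0, -47.0, 180.0)] * spec.groove_length, groove_seq(), "H")
    motif = build_chain(
        [(-57.0, -47.0, 180.0)] * spec.motif_length, spec.motif_sequence, "P"
    )

    def align_to_axis(chain: Chain, target_origin: np.ndarray, flip: bool) -> None:
        centroid, axis = _helix_axis(chain)
        target_axis = np.array([1.0, 0.0, 0.0]) * (-1.0 if flip else 1.0)
        v = np.cross(axis, target_axis)
        c = float(np.dot(axis, target_axis))
        if np.linalg.norm(v) < 1e-12:
            R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            R = np.eye(3) + vx + vx @ vx * ((1 - c) / (np.linalg.norm(v) ** 2))
        for res in chain.residues:
            for name in res.atoms:
                res.atoms[name] = R @ (res.atoms[name] - centroid) + target_origin

    half = spec.groove_separation / 2.0
    align_to_axis(g1, np.array([0.0, 0.0, -half]), flip=False)
    align_to_axis(g2, np.array([0.0, 0.0, half]), flip=True)
    align_to_axis(motif, np.array([0.0, spec.motif_offset, 0.0]), flip=False)
    s = Structure([g1, g2, motif], {"entry_id": "TOY"})
    return s


# -- sequence lineages (synthetic stand-ins) -------------------------------


def lineage_sequences() -> dict[str, ProteinSequence]:
    """SYNTHETIC stand-in binder lineages with the published Hamming structure.

    Two lineages of three-helix-bundle binder sequences are generated
    deterministically: the BAK-binder lineage (CDP02 -> aBAK1 -> aBAK2,
    length 118: 10 then 12 substitutions at disjoint positions, so the
    precursor-to-final distance is 22) and the BAX-binder lineage
    (CDP01 -> aBAX1 -> aBAX2, length 117: 8 then 10, total 18). The lengths
    are the unique ones consistent with all published rounded percentages
    (10/19/8% and 9/15/7%). These are stand-ins for comparison logic, not
    the deposited sequences.
    """
    rng = np.random.default_rng(20240917)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

    def make_lineage(names: tuple[str, str, str], length: int, n1: int, n2: int):
        parent = rng.choice(aas, size=length)
        positions = rng.choice(length, size=n1 + n2, replace=False)
        v1 = parent.copy()
        for p in positions[:n1]:
            v1[p] = rng.choice([a for a in aas if a != parent[p]])
        v2 = v1.copy()
        for p in positions[n1:]:
            v2[p] = rng.choice([a for a in aas if a != v1[p]])
        return {
            names[0]: ProteinSequence(names[0], "".join(parent)),
            names[1]: ProteinSequence(names[1], "".join(v1)),
            names[2]: ProteinSequence(names[2], "".join(v2)),
        }

    out = {}
    out.update(make_lineage(("CDP02", "aBAK1", "aBAK2"), 118, 10, 12))
    out.update(make_lineage(("CDP01", "aBAX1", "aBAX2"), 117, 8, 10))
    return out


# -- SSM pool simulation ---------------------------------------------------


def simulate_ssm_pools(
    parent: ProteinSequence,
    true_effects: dict[Mutation, tuple[float, float]],
    depth: int = 100_000,
    seed: int = 0,
    gate: float = 2.0,
) -> tuple[PoolCounts, PoolCounts, PoolCounts, dict]:
    """Simulate naive + affinity-sorted + specificity-sorted SSM pools.

    The naive pool is a multinomial over all single substitutions of the
    parent (uniform frequencies with mild lognormal noise). Each sorted pool
    passes variants through a logistic FACS gate on the relevant planted
    effect: survival probability sigmoid(effect - gate), so neutral variants
    survive at sigmoid(-gate) and strongly improved ones near 1. Returns the
    three pools plus a ground-truth dict with planted effects and the exact
    sampling probabilities.
    """
    if depth < 1000:
        raise ValueError("depth must be >= 1000")
    rng = np.random.default_rng(seed)
    muts: list[Mutation] = [
        (i, parent[i - 1], aa)
        for i in range(1, len(parent) + 1)
        for aa in "ACDEFGHIKLMNPQRSTVWY"
        if aa != parent[i - 1]
    ]
    base = np.exp(rng.normal(0.0, 0.3, size=len(muts)))
    naive_p = base / base.sum()
    naive_counts = rng.multinomial(depth, naive_p)

    def sigmoid(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-x))

    def sorted_pool(which: int, condition: str) -> PoolCounts:
        eff = np.array([true_effects.get(m, (0.0, 0.0))[which] for m in muts])
        survive = sigmoid(eff - gate)
        w = naive_p * survive
        p = w / w.sum()
        counts = rng.multinomial(depth, p)
        return PoolCounts(
            f"{condition}_pool", condition,
            {m: int(c) for m, c in zip(muts, counts)},
        )

    naive = PoolCounts(
        "naive_pool", "naive", {m: int(c) for m, c in zip(muts, naive_counts)}
    )
    aff = sorted_pool(0, "affinity_sort")
    spec = sorted_pool(1, "specificity_sort")
    truth = {
        "effects": dict(true_effects),
        "mutations": muts,
        "naive_probabilities": {m: float(p) for m, p in zip(muts, naive_p)},
        "gate": gate,
    }
    return naive, aff, spec, truth


def reads_from_counts(parent: ProteinSequence, pool: PoolCounts) -> list[str]:
    """Expand a count table back into explicit amino-acid reads (oracle aid)."""
    reads = [parent.residues] * pool.wildtype
    for (pos, _frm, to), c in sorted(pool.counts.items()):
        seq = parent.residues[: pos - 1] + to + parent.residues[pos:]
        reads.extend([seq] * c)
    return reads


# -- liposome trace simulation --------------------------------------------


def simulate_liposome_traces(
    p: MechanismParams,
    doses: np.ndarray,
    timepoints: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
    fmin: float = 100.0,
    fmax: float = 1100.0,
    tau: float = 25.0 * 60.0,
) -> dict:
    """Per-dose fluorescence time courses plus Fmin/Fmax control channels.

    Each trace rises exponentially (time constant ``tau`` seconds) toward the
    endpoint implied by the equilibrium mechanism at that dose; the endpoint
    of the noiseless trace equals the model release exactly. Controls: a
    buffer+liposome channel at Fmin and a detergent channel at Fmax.
    """
    doses = np.asarray(doses, float)
    if timepoints is None:
        timepoints = np.arange(0.0, 121.0, 2.0) * 60.0  # every 2 min for 120 min
    timepoints = np.asarray(timepoints, float)
    rng = np.random.default_rng(seed)
    release = simulate_dose_response(p, doses)
    shape = 1.0 - np.exp(-timepoints / tau)
    shape = shape / shape[-1]  # endpoint hits the model value exactly
    traces = {}
    for dose, rel in zip(doses, release):
        f = fmin + (rel / 100.0) * (fmax - fmin) * shape
        if noise > 0:
            f = f + rng.normal(0.0, noise * (fmax - fmin) / 100.0, size=f.shape)
        traces[float(dose)] = f
    return {
        "time_s": timepoints,
        "traces": traces,
        "fmin": fmin,
        "fmax": fmax,
        "release_true": {float(d): float(r) for d, r in zip(doses, release)},
    }
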