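"""Motif grafting: thread a BH3-like helical motif onto a scaffold.

The stage mirrors helix-on-helix motif transplantation with full-backbone
alignment: prepare a target/motif input pair from a bound complex (motif
reduced to backbone + CB, non-hotspot identities masked to alanine), scan
every contiguous scaffold window of the motif's length for geometric
compatibility (full-backbone RMSD <= 3.0 A, endpoint RMSD <= 2.0 A by
default), clash-test the posed scaffold against the target with side chains
reduced to glycine, and emit grafted complexes with hotspot identities
threaded and the rest of the scaffold reverted to its native sequence.

Default hotspots are motif positions 1, 5, 8, 9, 10 (the conserved BH3
residues h1, h2, h3, h3+1, h3+2 - Ile, Leu, Ile, Gly, Asp in the canonical
13-residue motif).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .sidechains import vdw_radius
from .structio import (
    BACKBONE_ATOMS,
    Chain,
    ONE_TO_THREE,
    ProteinSequence,
    Residue,
    Structure,
    THREE_TO_ONE,
)
from .superpose import Superposition, kabsch

__all__ = [
    "Motif",
    "GraftConfig",
    "GraftSolution",
    "prepare_context_motif",
    "find_graft_sites",
    "clash_score",
    "apply_graft",
]

DEFAULT_HOTSPOTS = (1, 5, 8, 9, 10)


@dataclasses.dataclass
class Motif:
    """Backbone(+CB) of the helical motif with hotspot positions/identities."""

    backbone: np.ndarray  # (L, 4, 3): N, CA, C, O per residue
    cb: np.ndarray  # (L, 3); rows may be NaN for glycine
    hotspot_indices: tuple[int, ...]  # 1-based within the motif
    hotspot_identities: tuple[str, ...]  # 1-letter codes
    numbers: tuple[int, ...] = ()  # author numbers of the source residues

    def __post_init__(self) -> None:
        L = self.length
        idx = self.hotspot_indices
        if any(not 1 <= i <= L for i in idx) or list(idx) != sorted(set(idx)):
            raise ValueError("hotspot indices must be strictly increasing within [1, L]")
        if len(self.hotspot_identities) != len(idx):
            raise ValueError("hotspot identities/indices length mismatch")

    @property
    def length(self) -> int:
        return self.backbone.shape[0]

    @property
    def sequence(self) -> str:
        """Alanine-masked motif sequence with hotspot identities preserved."""
        seq = ["A"] * self.length
        for i, aa in zip(self.hotspot_indices, self.hotspot_identities):
            seq[i - 1] = aa
        return "".join(seq)


@dataclasses.dataclass
class GraftConfig:
    """Geometric tolerances and clash rule for the graft scan."""

    full_bb_rmsd_tol: float = 3.0  # A
    endpoint_rmsd_tol: float = 2.0  # A (N/C-terminal residues, same transform)
    clash_cutoff: int = 0
    clash_test_residue: str = "GLY"  # scaffold side chains reduced for the clash test
    clash_vdw_relief: float = 0.6  # A subtracted from summed vdW radii
    full_backbone_alignment: bool = True
    revert_to_native: bool = True

    def __post_init__(self) -> None:
        if self.full_bb_rmsd_tol <= 0 or self.endpoint_rmsd_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.clash_test_residue != "GLY":
            raise ValueError("only the glycine clash test is supported")


@dataclasses.dataclass
class GraftSolution:
    """One accepted placement: scaffold window + transform into the context frame."""

    window_start: int  # 0-based scaffold residue index
    length: int
    placement: Superposition  # maps scaffold coordinates onto the motif frame
    full_bb_rmsd: float
    endpoint_rmsd: float
    clash_count: int | None = None  # filled by clash_score
    complex: Structure | None = None  # filled by apply_graft


def _backbone_array(residues: list[Residue]) -> np.ndarray:
    rows = []
    for res in residues:
        try:
            rows.append([res.atoms[a] for a in BACKBONE_ATOMS])
        except KeyError as exc:
            raise ValueError(f"residue {res.number} missing backbone atom {exc}") from exc
    return np.array(rows)


def prepare_context_motif(
    complex: Structure,
    peptide_chain: str,
    motif_span: tuple[int, int],
    hotspot_indices: tuple[int, ...] = DEFAULT_HOTSPOTS,
    hotspot_identities: tuple[str, ...] | None = None,
) -> tuple[Structure, Motif]:
    """Split a bound complex into design inputs: target context + masked motif.

    The bound peptide span (author numbering, inclusive) is reduced to
    backbone + C-beta; hotspot identities are read from the peptide (or
    overridden) and every other motif position is masked to alanine. The
    context keeps all remaining chains unchanged.
    """
    lo, hi = motif_span
    pep = [r for r in complex.chain(peptide_chain).polymer() if lo <= r.number <= hi]
    L = len(pep)
    if L == 0:
        raise ValueError(f"span {motif_span} selects no residues on chain {peptide_chain}")
    if L < max(hotspot_indices):
        raise ValueError(
            f"motif span of length {L} shorter than max hotspot index {max(hotspot_indices)}"
        )
    backbone = _backbone_array(pep)
    cb = np.full((L, 3), np.nan)
    for i, res in enumerate(pep):
        if "CB" in res.atoms:
            cb[i] = res.atoms["CB"]
    if hotspot_identities is None:
        hotspot_identities = tuple(pep[i - 1].one_letter for i in hotspot_indices)
    motif = Motif(
        backbone, cb, tuple(hotspot_indices), tuple(hotspot_identities),
        numbers=tuple(r.number for r in pep),
    )
    context = Structure(
        [ch.copy() for ch in complex.chains if ch.id != peptide_chain],
        dict(complex.metadata),
    )
    return context, motif


def find_graft_sites(
    motif: Motif, scaffold: Structure, cfg: GraftConfig | None = None
) -> list[GraftSolution]:
    """Scan every contiguous scaffold window for graft-compatible geometry.

    For each window of the motif's length, the window backbone (N, CA, C, O
    of all residues) is least-squares superposed onto the motif backbone
    (full-backbone alignment); the endpoint RMSD is evaluated over the first
    and last residues' backbone atoms under that same transform, without
    refitting. A window is accepted iff both RMSDs are within tolerance.
    Results are sorted ascending by full-backbone RMSD, ties broken by
    window start (N to C scan order).
    """
    cfg = cfg or GraftConfig()
    if len(scaffold.chains) != 1:
        raise ValueError("scaffold must be a single polymer chain")
    residues = scaffold.chains[0].polymer()
    L = motif.length
    if len(residues) < L:
        warnings.warn("scaffold shorter than motif; no graft sites", stacklevel=2)
        return []
    motif_bb = motif.backbone.reshape(-1, 3)
    end_idx = np.concatenate([np.arange(4), np.arange(4 * (L - 1), 4 * L)])
    solutions = []
    for start in range(len(residues) - L + 1):
        window = residues[start : start + L]
        try:
            win_bb = _backbone_array(window).reshape(-1, 3)
        except ValueError:
            continue
        sup = kabsch(win_bb, motif_bb)
        if sup.rmsd > cfg.full_bb_rmsd_tol:
            continue
        moved = sup.apply(win_bb)
        diff = moved[end_idx] - motif_bb[end_idx]
        endpoint_rmsd = float(np.sqrt((diff**2).sum() / len(end_idx)))
        if endpoint_rmsd > cfg.endpoint_rmsd_tol:
            continue
        solutions.append(
            GraftSolution(start, L, sup, sup.rmsd, endpoint_rmsd)
        )
    solutions.sort(key=lambda s: (s.full_bb_rmsd, s.window_start))
    return solutions


def clash_score(
    context: Structure,
    posed_scaffold: Structure,
    cfg: GraftConfig | None = None,
    exclude_window: tuple[int, int] | None = None,
) -> int:
    """Count hard overlaps between the context and the glycine-reduced scaffold.

    The scaffold is reduced to backbone N, CA, C, O (the glycine clash-test
    semantics taken literally: glycine has no C-beta). A pair clashes when
    its distance is below r_vdw_i + r_vdw_j - relief (default relief 0.6 A).
    ``exclude_window`` (0-based start, length) removes the grafted-window
    backbone - the atoms that legitimately replace the native bound peptide -
    from the count.
    """
    cfg = cfg or GraftConfig()
    ctx_atoms: list[tuple[str, np.ndarray]] = []
    for ch in context.chains:
        for res in ch.polymer():
            for name, xyz in res.atoms.items():
                if not name.startswith("H"):
                    ctx_atoms.append((name, xyz))
    sc_atoms: list[tuple[str, np.ndarray]] = []
    for ch in posed_scaffold.chains:
        for i, res in enumerate(ch.polymer()):
            if exclude_window is not None:
                s0, L = exclude_window
                if s0 <= i < s0 + L:
                    continue
            for name in BACKBONE_ATOMS:
                if name in res.atoms:
                    sc_atoms.append((name, res.atoms[name]))
    if not ctx_atoms or not sc_atoms:
        return 0
    ctx_xyz = np.array([a[1] for a in ctx_atoms])
    sc_xyz = np.array([a[1] for a in sc_atoms])
    ctx_r = np.array([vdw_radius(a[0]) for a in ctx_atoms])
    sc_r = np.array([vdw_radius(a[0]) for a in sc_atoms])
    max_cut = ctx_r.max() + sc_r.max() - cfg.clash_vdw_relief
    pairs = cKDTree(ctx_xyz).query_ball_tree(cKDTree(sc_xyz), r=max_cut)
    count = 0
    for i, js in enumerate(pairs):
        for j in js:
            cutoff = ctx_r[i] + sc_r[j] - cfg.clash_vdw_relief
            if np.linalg.norm(ctx_xyz[i] - sc_xyz[j]) < cutoff:
                count += 1
    return count


def apply_graft(
    sol: GraftSolution,
    motif: Motif,
    context: Structure,
    scaffold: Structure,
    scaffold_native_seq: ProteinSequence | None = None,
    binder_chain_id: str = "B",
) -> Structure:
    """Pose the scaffold into the context frame and thread the graft sequence.

    Hotspot identities are written onto the corresponding scaffold window
    positions (hotspot wins on conflict, with a note in the provenance);
    every other scaffold position keeps its native identity (the
    revert-to-native semantics). The result is a complex Structure carrying
    a provenance record (window, RMSDs, clash count) in its metadata, which
    round-trips through PDB REMARK lines.
    """
    posed = scaffold.copy()
    sup = sol.placement
    for _, _, _name, xyz in list(posed.iter_atoms()):
        xyz[:] = sup.rotation @ xyz + sup.translation
    chain = posed.chains[0]
    chain.id = binder_chain_id
    native = scaffold_native_seq or ProteinSequence(
        "scaffold", "".join(r.one_letter for r in scaffold.chains[0].polymer())
    )
    conflicts = []
    for k, aa in zip(motif.hotspot_indices, motif.hotspot_identities):
        pos = sol.window_start + (k - 1)
        res = chain.polymer()[pos]
        native_aa = native[pos]
        if native_aa != aa:
            conflicts.append(f"{native_aa}{pos + 1}{aa}")
        if res.name != ONE_TO_THREE[aa]:
            _retype(res, ONE_TO_THREE[aa])
    new_chains = [ch.copy() for ch in context.chains] + [chain]
    out = Structure(new_chains, dict(context.metadata))
    out.metadata["provenance"] = [
        f"GRAFT window_start={sol.window_start} length={sol.length}",
        f"GRAFT full_bb_rmsd={sol.full_bb_rmsd:.3f} endpoint_rmsd={sol.endpoint_rmsd:.3f}",
        f"GRAFT clash_count={sol.clash_count if sol.clash_count is not None else 'NA'}",
    ] + ([f"GRAFT hotspot_overrides={','.join(conflicts)}"] if conflicts else [])
    sol.complex = out
    return out


def _retype(res: Residue, new_name: str) -> None:
    """Swap residue identity keeping backbone + CB only (design fills the rest)."""
    keep = {k: v for k, v in res.atoms.items() if k in ("N", "CA", "C", "O", "CB")}
    if new_name == "GLY":
        keep.pop("CB", None)
    res.name = new_name
    res.atoms = keep
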