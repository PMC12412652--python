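"""Shared fixtures: toy structures generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from bh3forge.motif_graft import GraftConfig, apply_graft, find_graft_sites, prepare_context_motif
from bh3forge.structio import Chain, Residue, Structure
from bh3forge.synthetic_data import (
    ToyComplexSpec,
    build_scaffold_bundle,
    build_toy_complex,
)


@pytest.fixture(scope="session")
def toy_complex() -> Structure:
    return build_toy_complex(ToyComplexSpec())


@pytest.fixture(scope="session")
def context_and_motif(toy_complex):
    return prepare_context_motif(toy_complex, "P", (1, 13))


@pytest.fixture(scope="session")
def scaffold() -> Structure:
    return build_scaffold_bundle()


@pytest.fixture(scope="session")
def graft_complex(context_and_motif, scaffold) -> Structure:
    """A grafted complex with the binder threaded into the toy groove."""
    context, motif = context_and_motif
    sols = find_graft_sites(motif, scaffold, GraftConfig())
    # pick a window inside the middle helix so the binder packs in the groove
    sol = next(s for s in sols if s.window_start >= 18)
    return apply_graft(sol, motif, context, scaffold)


@pytest.fixture(scope="session")
def graft_solution(context_and_motif, scaffold):
    context, motif = context_and_motif
    sols = find_graft_sites(motif, scaffold, GraftConfig())
    return next(s for s in sols if s.window_start >= 18)


def make_structure(chains: dict[str, list[tuple[str, dict[str, np.ndarray]]]]) -> Structure:
    """Hand-build a Structure from {chain: [(resname, {atom: xyz}), ...]}."""
    out = []
    for cid, residues in chains.items():
        out.append(
            Chain(
                cid,
                [
                    Residue(name, i + 1, {k: np.asarray(v, float) for k, v in atoms.items()})
                    for i, (name, atoms) in enumerate(residues)
                ],
            )
        )
    return Structure(out)
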