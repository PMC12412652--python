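"""Structure and sequence I/O and the residue/atom data model.

The data model is deliberately small: ordered chains of residues, each
residue a mapping atom-name -> 3-vector (ångström), with author residue
numbering preserved so that residue citations like "I50" or "BAK 90-141"
map directly onto the objects. PDB parsing and serialization are delegated
to gemmi; FASTA to Biopython.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .geometry import dihedral

__all__ = [
    "Residue",
    "Chain",
    "Structure",
    "ProteinSequence",
    "StructureError",
    "read_structure",
    "write_structure",
    "extract_sequence",
    "mutation_count",
    "read_fasta",
    "write_fasta",
    "BACKBONE_ATOMS",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common dialect: selenomethionine read as methionine
    "MSE": "M",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structures."""


@dataclasses.dataclass
class Residue:
    """One residue: 3-letter name, author number, atom-name -> coordinate map."""

    name: str
    number: int
    atoms: dict[str, np.ndarray]
    insertion_code: str = ""
    het: bool = False

    def coord(self, atom: str) -> np.ndarray:
        return self.atoms[atom]

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def copy(self) -> "Residue":
        return Residue(
            self.name,
            self.number,
            {k: v.copy() for k, v in self.atoms.items()},
            self.insertion_code,
            self.het,
        )


@dataclasses.dataclass
class Chain:
    id: str
    residues: list[Residue]

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def polymer(self) -> list[Residue]:
        return [r for r in self.residues if not r.het]

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])


@dataclasses.dataclass
class Structure:
    chains: list[Chain]
    metadata: dict = dataclasses.field(default_factory=dict)

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.id == chain_id:
                return ch
        raise StructureError(f"no chain {chain_id!r} in structure")

    def chain_ids(self) -> list[str]:
        return [ch.id for ch in self.chains]

    def copy(self) -> "Structure":
        return Structure([ch.copy() for ch in self.chains], dict(self.metadata))

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, str, np.ndarray]]:
        for ch in self.chains:
            for res in ch.residues:
                for name, xyz in res.atoms.items():
                    yield ch, res, name, xyz

    def heavy_coords(self, polymer_only: bool = True) -> np.ndarray:
        pts = []
        for ch in self.chains:
            for res in ch.residues:
                if polymer_only and res.het:
                    continue
                for name, xyz in res.atoms.items():
                    if not name.startswith("H"):
                        pts.append(xyz)
        return np.array(pts) if pts else np.empty((0, 3))

    def validate(self) -> None:
        ids = self.chain_ids()
        if len(set(ids)) != len(ids):
            raise StructureError(f"duplicate chain ids: {ids}")
        for ch in self.chains:
            seen = set()
            for res in ch.residues:
                key = (res.number, res.insertion_code, res.het)
                if key in seen:
                    raise StructureError(
                        f"duplicate residue {res.number}{res.insertion_code} in chain {ch.id}"
                    )
                seen.add(key)
                for xyz in res.atoms.values():
                    if not np.all(np.isfinite(xyz)):
                        raise StructureError(
                            f"non-finite coordinates at {ch.id}/{res.number}"
                        )

    # -- backbone dihedrals ------------------------------------------------

    def backbone_dihedrals(self, chain_id: str) -> list[dict[str, float | None]]:
        """Per-residue phi/psi/omega (degrees) for a polymer chain.

        omega of residue i is the CA(i)-C(i)-N(i+1)-CA(i+1) dihedral, defined
        only when a following residue exists.
        """
        res = [r for r in self.chain(chain_id).polymer() if r.has_backbone()]
        out: list[dict[str, float | None]] = []
        for i, r in enumerate(res):
            phi = psi = omega = None
            if i > 0 and "C" in res[i - 1].atoms:
                phi = dihedral(res[i - 1].atoms["C"], r.atoms["N"], r.atoms["CA"], r.atoms["C"])
            if i + 1 < len(res):
                nxt = res[i + 1]
                psi = dihedral(r.atoms["N"], r.atoms["CA"], r.atoms["C"], nxt.atoms["N"])
                omega = dihedral(r.atoms["CA"], r.atoms["C"], nxt.atoms["N"], nxt.atoms["CA"])
            out.append({"phi": phi, "psi": psi, "omega": omega})
        return out


@dataclasses.dataclass
class ProteinSequence:
    """Plain one-letter protein sequence with an identifier."""

    id: str
    residues: str

    ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

    def __post_init__(self) -> None:
        bad = set(self.residues) - self.ALPHABET
        if bad:
            raise ValueError(f"non-canonical residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i) -> str:
        return self.residues[i]


# -- PDB I/O ---------------------------------------------------------------


def _pick_altloc(atoms: Iterable[gemmi.Atom]) -> list[gemmi.Atom]:
    """Resolve alternate locations: highest occupancy, ties to letter 'A' first."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for at in atoms:
        by_name.setdefault(at.name, []).append(at)
    picked = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occ, a.altloc or "A"))
        picked.append(group[0])
    return picked


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a PDB file into the Structure data model.

    Polymer chains are retained in author order; heteroatom residues (waters,
    ligands) are kept but flagged ``het``. Alternate locations resolve to the
    highest-occupancy conformer. A file with no polymer residues raises
    :class:`StructureError`.
    """
    if format != "pdb":
        raise ValueError(f"unsupported format {format!r}; only 'pdb' is supported")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]
    chains: list[Chain] = []
    n_polymer = 0
    for gch in model:
        residues: list[Residue] = []
        for gres in gch:
            het = gres.het_flag == "H" and gres.name not in THREE_TO_ONE
            atoms: dict[str, np.ndarray] = {}
            for at in _pick_altloc(gres):
                atoms[at.name] = np.array([at.pos.x, at.pos.y, at.pos.z])
            residues.append(
                Residue(gres.name, gres.seqid.num, atoms, gres.seqid.icode.strip(), het)
            )
            if not het:
                n_polymer += 1
        if residues:
            chains.append(Chain(gch.name, residues))
    if n_polymer == 0:
        raise StructureError(f"{path}: structure contains no polymer residues")
    meta = {"entry_id": st.name, "space_group": st.spacegroup_hm}
    remarks = [ln for ln in st.raw_remarks if "BH3FORGE" in ln]
    if remarks:
        meta["provenance"] = [ln.rstrip() for ln in remarks]
    return Structure(chains, meta)


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a Structure as PDB.

    Round-trips chain/residue/atom content and coordinates at PDB precision
    (3 decimals). Atom serial numbers beyond 99999 use gemmi's hybrid-36
    convention. Provenance strings in ``metadata['provenance']`` are emitted
    as REMARK records.
    """
    s.validate()
    st = gemmi.Structure()
    st.name = str(s.metadata.get("entry_id", "XXXX"))
    model = gemmi.Model("1")
    for ch in s.chains:
        gch = gemmi.Chain(ch.id)
        serial = 1
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            gres.het_flag = "H" if res.het else "A"
            for name, xyz in res.atoms.items():
                at = gemmi.Atom()
                at.name = name
                at.pos = gemmi.Position(*[float(v) for v in xyz])
                at.occ = 1.0
                at.element = gemmi.Element(_element_of(name))
                at.serial = serial
                serial += 1
                gres.add_atom(at)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    pdb_text = st.make_pdb_string()
    remarks = s.metadata.get("provenance", [])
    if remarks:
        remark_block = "".join(f"REMARK 999 BH3FORGE {r}\n" for r in remarks)
        pdb_text = remark_block + pdb_text
    Path(path).write_text(pdb_text)


def _element_of(atom_name: str) -> str:
    stripped = atom_name.strip("0123456789")
    if not stripped:
        return "C"
    first = stripped[0]
    return first if first in "CNOSHP" else "C"


def extract_sequence(s: Structure, chain: str) -> ProteinSequence:
    """One-letter sequence of a chain in residue order; nonstandard -> X.

    MSE is read as M (selenomethionine); other nonstandard polymer residues
    become X and are listed in a substitution note on the returned id.
    """
    ch = s.chain(chain)
    letters = []
    subs = []
    for res in ch.polymer():
        one = THREE_TO_ONE.get(res.name)
        if one is None:
            letters.append("X")
            subs.append(f"{res.name}{res.number}->X")
        else:
            if res.name == "MSE":
                subs.append(f"MSE{res.number}->M")
            letters.append(one)
    seq_id = chain if not subs else f"{chain} [{','.join(subs)}]"
    return ProteinSequence(seq_id, "".join(letters))


# -- sequence comparison ---------------------------------------------------


def mutation_count(a: ProteinSequence, b: ProteinSequence) -> tuple[int, int]:
    """Hamming distance between equal-length sequences and rounded percent.

    Returns ``(count, percent)`` where percent = round(100*count/length) to
    the nearest integer (the convention used when reporting lineage
    divergence, e.g. "12 mutations (10%)"). Unequal lengths are an error:
    these are point-mutation lineages, not alignments.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sequence")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    count = sum(1 for x, y in zip(a.residues, b.residues) if x != y)
    percent = int(round(100.0 * count / len(a)))
    return count, percent


# -- FASTA -----------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    return [
        ProteinSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")
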