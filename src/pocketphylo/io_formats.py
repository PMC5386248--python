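"""Readers, writers and in-memory containers for the standard formats.

Conventions used throughout the package:

* residue positions are 1-based (PDB author numbering is kept verbatim);
* alignment columns are 1-based;
* the only gap symbol is ``'-'`` ('.' is normalised to '-' on read);
* coordinates are in Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import gemmi
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateIdError,
    EmptyModelError,
    IllegalCharacterError,
    MalformedLineError,
    RaggedAlignmentError,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: 3-letter -> 1-letter code for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Two-character element symbols recognised when inferring elements from
# atom names (metals and halogens commonly seen in PDB files). "CA"/"NA"
# are deliberately absent: in protein chains those names are almost always
# the alpha-carbon / a nitrogen, not calcium / sodium.
_TWO_CHAR_ELEMENTS = {
    "FE", "ZN", "MG", "MN", "CL", "BR", "CU", "NI", "CO",
    "SE", "CD", "HG", "MO",
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure model (PDB-style fields, coordinates in Å)."""

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    x: float
    y: float
    z: float

    def __post_init__(self):
        if not self.element:
            raise ValueError("element must be non-empty")
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValueError("coordinates must be finite")


@dataclass
class StructureModel:
    """One 3-D model of one protein domain (an ordered list of atoms)."""

    protein_id: str
    model_id: str
    atoms: list[AtomRecord]

    def __post_init__(self):
        if not self.atoms:
            raise EmptyModelError(
                f"{self.protein_id}/{self.model_id}: structure has no atoms"
            )
        seen = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_index, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in model {self.model_id}")
            seen.add(key)

    def residues(self) -> list[tuple[str, int, str]]:
        """(chain_id, residue_index, residue_name) in order of first appearance."""
        out, seen = [], set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_index)
            if key not in seen:
                seen.add(key)
                out.append((a.chain_id, a.residue_index, a.residue_name))
        return out

    def one_letter_sequence(self) -> str:
        """Extracted sequence in residue order; unknown resnames become 'X'."""
        return "".join(
            THREE_TO_ONE.get(resn, "X") for _, _, resn in self.residues()
        )


class Msa:
    """A multiple sequence alignment with residue-position <-> column maps.

    ``pos_to_col[i]`` maps the 1-based residue position of row *i* to its
    1-based alignment column; ``col_to_pos[i]`` is the inverse. Gapped
    columns are simply absent from the maps.
    """

    def __init__(self, sequence_ids: list[str], rows: list[str]):
        if len(sequence_ids) != len(rows):
            raise ValueError("sequence_ids and rows differ in length")
        if len(set(sequence_ids)) != len(sequence_ids):
            raise DuplicateIdError("duplicate sequence ids in alignment")
        rows = [r.upper().replace(".", GAP) for r in rows]
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            bad = [
                sid for sid, r in zip(sequence_ids, rows)
                if len(r) != len(rows[0])
            ]
            raise RaggedAlignmentError(bad)
        for sid, r in zip(sequence_ids, rows):
            illegal = set(r) - set(AMINO_ACIDS) - {GAP, "X"}
            if illegal:
                raise IllegalCharacterError(
                    f"illegal character {sorted(illegal)[0]!r} in row {sid!r}"
                )
        self.sequence_ids = list(sequence_ids)
        self.rows = rows
        self.pos_to_col: list[dict[int, int]] = []
        self.col_to_pos: list[dict[int, int]] = []
        for r in rows:
            p2c: dict[int, int] = {}
            c2p: dict[int, int] = {}
            pos = 0
            for col, ch in enumerate(r, start=1):
                if ch != GAP:
                    pos += 1
                    p2c[pos] = col
                    c2p[col] = pos
            self.pos_to_col.append(p2c)
            self.col_to_pos.append(c2p)
        self._index = {sid: i for i, sid in enumerate(self.sequence_ids)}

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row_index(self, sequence_id: str) -> int:
        return self._index[sequence_id]

    def ungapped(self, sequence_id: str) -> str:
        return self.rows[self.row_index(sequence_id)].replace(GAP, "")

    def __eq__(self, other):
        return (
            isinstance(other, Msa)
            and self.sequence_ids == other.sequence_ids
            and self.rows == other.rows
        )


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def infer_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name when the element field is blank.

    Leading digits are stripped (e.g. ``1HB``); a two-character leading pair
    that names a metal/halogen is used as-is, otherwise the first letter wins.
    """
    s = atom_name.strip().lstrip("0123456789")
    if not s:
        raise MalformedLineError(f"cannot infer element from atom name {atom_name!r}")
    if s[:2].upper() in _TWO_CHAR_ELEMENTS:
        return s[:2].capitalize()
    return s[0].upper()


def _validate_pdb_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise MalformedLineError("truncated ATOM/HETATM record", lineno)
            try:
                int(line[22:26])
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise MalformedLineError(
                    f"unparseable numeric field in {line.rstrip()!r}", lineno
                ) from None


def read_pdb(
    path: str | Path,
    chain_filter: str | None = None,
    protein_id: str | None = None,
    model_id: str | None = None,
) -> StructureModel:
    """Read one structure model from a PDB file.

    Waters (HOH) are dropped, hydrogens kept, and alternate locations are
    resolved to the highest-occupancy conformer (first on ties). Only the
    first MODEL of a multi-model file is read.
    """
    path = Path(path)
    _validate_pdb_lines(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise MalformedLineError(f"gemmi failed to parse {path}: {exc}") from exc
    st.setup_entities()
    atoms: list[AtomRecord] = []
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    model = st[0]
    for chain in model:
        if chain_filter is not None and chain.name != chain_filter:
            continue
        for residue in chain:
            if residue.name == "HOH":
                continue
            # resolve altlocs per atom name: highest occupancy, then first
            by_name: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = by_name.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    by_name[atom.name] = atom
            for atom in residue:  # keep original atom order
                chosen = by_name.pop(atom.name, None)
                if chosen is None:
                    continue
                element = chosen.element.name
                if not element or element == "X":
                    element = infer_element(chosen.name)
                atoms.append(
                    AtomRecord(
                        serial=chosen.serial,
                        name=chosen.name,
                        element=element,
                        residue_index=residue.seqid.num,
                        residue_name=residue.name,
                        chain_id=chain.name,
                        x=chosen.pos.x,
                        y=chosen.pos.y,
                        z=chosen.pos.z,
                    )
                )
    if not atoms:
        raise EmptyModelError(
            f"{path}: no ATOM records survived filters (chain_filter={chain_filter!r})"
        )
    return StructureModel(
        protein_id=protein_id or path.stem,
        model_id=model_id or path.stem,
        atoms=atoms,
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a single-model PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = model.protein_id
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    for a in model.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        key = (a.chain_id, a.residue_index)
        if key not in residues:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_index, " ")
            chains[a.chain_id].add_residue(res)
            # re-fetch: gemmi copies on add
            residues[key] = chains[a.chain_id][-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.serial = a.serial
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(a.x, a.y, a.z)
        atom.occ = 1.0
        residues[key].add_atom(atom)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    doc_path = Path(path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(doc_path))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read amino-acid FASTA records as (id, sequence) pairs.

    Sequences are uppercased; a single trailing '*' (stop) is stripped.
    Duplicate ids and non-amino-acid characters are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        illegal = set(seq) - set(AMINO_ACIDS) - {"X"}
        if illegal:
            raise IllegalCharacterError(
                f"illegal character {sorted(illegal)[0]!r} in sequence {rec.id!r}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    seq_records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_alignment(path: str | Path) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa` (gap-aware)."""
    ids, rows, seen = [], [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        ids.append(rec.id)
        rows.append(str(rec.seq))
    return Msa(ids, rows)


def write_alignment(msa: Msa, path: str | Path) -> None:
    write_fasta(list(zip(msa.sequence_ids, msa.rows)), path)


# ---------------------------------------------------------------------------
# Newick (dendropy.Tree is the in-memory tree type everywhere)
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Write a dendropy Tree; internal-node support values become labels."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(newick_string(tree))


def newick_string(tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def read_newick(path_or_string: str | Path, is_string: bool = False):
    import dendropy

    if is_string:
        return dendropy.Tree.get(data=str(path_or_string), schema="newick",
                                 preserve_underscores=True)
    return dendropy.Tree.get(path=str(path_or_string), schema="newick",
                             preserve_underscores=True)
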