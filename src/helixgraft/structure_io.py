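"""Coordinate and sequence I/O plus the hierarchical structure model.

The coordinate model is a thin chain → residue → atom hierarchy carrying
author residue numbering, occupancies and B-factors — everything the
geometric and evaluation layers need, and nothing crystallographic beyond
that.  Parsing and fixed-column writing of PDB files is delegated to gemmi;
FASTA handling to Biopython.

Conventions used throughout the package:

* residue numbering is author (PDB) numbering, 1-based;
* residue spans in configs and function signatures are inclusive on both
  ends, e.g. ``(91, 94)`` names four residues;
* alternate locations are resolved at read time to the highest-occupancy
  conformer (ties broken by file order), so downstream geometry always sees
  a single conformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    EmptyStructureError,
    PDBParseError,
    SequenceValidationError,
)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "SequenceRecord",
    "read_pdb",
    "write_pdb",
    "read_fasta",
    "write_fasta",
    "AA_3TO1",
    "AA_1TO3",
]

# The 20 canonical amino acids (3-letter ↔ 1-letter).
AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

_WATER_NAMES = {"HOH", "WAT", "DOD"}
_SEQUENCE_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Atom:
    """A single atom: name, element, position (Å), occupancy, B-factor (Å²)."""

    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.bfactor < 0:
            raise ValueError(f"atom {self.name!r}: negative B-factor")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.pos.copy(), self.occupancy, self.bfactor)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """One residue: author number, insertion code, 3-letter name, ordered atoms."""

    seq_id: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    het: bool = False  # True for HETATM records (waters, ligands)

    def __post_init__(self):
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"residue {self.name}{self.seq_id}: duplicate atom names"
            )

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def copy(self) -> "Residue":
        return Residue(self.seq_id, self.name, [a.copy() for a in self.atoms],
                       self.insertion_code, self.het)

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.name in _WATER_NAMES

    @property
    def is_protein(self) -> bool:
        return self.name in AA_3TO1

    @property
    def one_letter(self) -> str:
        return AA_3TO1.get(self.name, "X")

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_ATOMS)


class Structure:
    """A coordinate model: ordered chains of ordered residues.

    Residues within a chain are kept in file order; ``(chain, seq_id,
    insertion_code)`` must be unique.
    """

    def __init__(self, id: str = "", chains: dict[str, list[Residue]] | None = None):
        self.id = id
        self.chains: dict[str, list[Residue]] = chains if chains is not None else {}
        self._check_unique()

    def _check_unique(self):
        for cid, residues in self.chains.items():
            keys = [r.key for r in residues]
            if len(keys) != len(set(keys)):
                raise ValueError(f"chain {cid}: duplicate residue identifiers")

    # -- construction helpers ------------------------------------------------
    def add_residue(self, chain_id: str, residue: Residue):
        residues = self.chains.setdefault(chain_id, [])
        if any(r.key == residue.key for r in residues):
            raise ValueError(
                f"chain {chain_id}: duplicate residue {residue.seq_id}{residue.insertion_code}"
            )
        residues.append(residue)

    def copy(self) -> "Structure":
        return Structure(self.id, {c: [r.copy() for r in rs] for c, rs in self.chains.items()})

    # -- queries -------------------------------------------------------------
    @property
    def n_residues(self) -> int:
        return sum(len(rs) for rs in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for rs in self.chains.values() for r in rs)

    def residues(self, chain_id: str | None = None):
        """Iterate residues, optionally restricted to one chain."""
        if chain_id is not None:
            yield from self.chains[chain_id]
        else:
            for rs in self.chains.values():
                yield from rs

    def get_residue(self, chain_id: str, seq_id: int, insertion_code: str = "") -> Residue | None:
        for r in self.chains.get(chain_id, []):
            if r.seq_id == seq_id and r.insertion_code == insertion_code:
                return r
        return None

    def iter_atoms(self, heavy_only: bool = False):
        """Yield ``(chain_id, residue, atom)`` triples."""
        for cid, rs in self.chains.items():
            for r in rs:
                for a in r.atoms:
                    if heavy_only and a.is_hydrogen:
                        continue
                    yield cid, r, a

    def protein_residue_count(self) -> int:
        """Number of standard amino-acid residues (waters/ligands excluded)."""
        return sum(1 for r in self.residues() if r.is_protein)

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chains[chain_id] if r.is_protein)

    def first_chain_id(self) -> str:
        if not self.chains:
            raise EmptyStructureError(f"structure {self.id!r} has no chains")
        return next(iter(self.chains))


@dataclass
class SequenceRecord:
    """A named 1-letter amino-acid sequence (canonical letters plus X)."""

    id: str
    sequence: str

    def __post_init__(self):
        bad = sorted(set(self.sequence) - _SEQUENCE_ALPHABET)
        if any(c.islower() for c in self.sequence):
            warnings.warn(f"record {self.id!r}: lowercase letters uppercased")
            self.sequence = self.sequence.upper()
            bad = sorted(set(self.sequence) - _SEQUENCE_ALPHABET)
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: illegal characters {''.join(bad)!r}", offending=bad
            )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _resolve_altlocs(atoms: list[tuple[str, Atom, float]]) -> list[Atom]:
    """Collapse alternate locations: keep the highest-occupancy conformer per
    atom name; ties go to the first encountered."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for _altloc, atom, occ in atoms:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif occ > best[atom.name].occupancy:
            best[atom.name] = atom
    return [best[n] for n in order]


def read_pdb(path) -> Structure:
    """Read a PDB coordinate file into a :class:`Structure`.

    Author numbering and file order are preserved.  Altlocs are resolved to
    the highest-occupancy conformer.  Multi-MODEL files are read as their
    first model with a warning (the use case is X-ray single-conformer
    models).
    """
    # Pre-validate coordinate fields: gemmi tolerates malformed numbers, but
    # silently garbled geometry is worse than a parse error.
    has_atom = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(("ATOM  ", "HETATM")):
                has_atom = True
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fld = line[lo:hi].strip()
                    try:
                        float(fld)
                    except ValueError:
                        raise PDBParseError(
                            f"{path}:{lineno}: malformed coordinate field {fld!r}"
                        ) from None
    if not has_atom:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinate records")
    if len(st) > 1:
        warnings.warn(f"{path}: {len(st)} models present; reading the first")
    model = st[0]
    out = Structure(id=st.name or str(path))
    n_atoms = 0
    for chain in model:
        cid = chain.name or "A"
        for res in chain:
            raw: list[tuple[str, Atom, float]] = []
            for at in res:
                raw.append((
                    at.altloc,
                    Atom(at.name, at.element.name,
                         np.array([at.pos.x, at.pos.y, at.pos.z]),
                         at.occ, max(at.b_iso, 0.0)),
                    at.occ,
                ))
            atoms = _resolve_altlocs(raw)
            n_atoms += len(atoms)
            out.add_residue(cid, Residue(
                seq_id=res.seqid.num,
                name=res.name,
                atoms=atoms,
                insertion_code=(res.seqid.icode or "").strip(),
                het=(res.het_flag == "H"),
            ))
    if n_atoms == 0:
        raise EmptyStructureError(f"{path}: model contains no atoms")
    return out


def write_pdb(structure: Structure, path) -> None:
    """Write a :class:`Structure` as a fixed-column PDB file.

    Coordinates survive a round-trip to 0.001 Å and B-factors to 0.01 Å²
    (the fixed-column field widths).  Residue numbers above 9999 do not fit
    the format and raise.
    """
    if structure.n_atoms == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    for r in structure.residues():
        if r.seq_id > 9999 or r.seq_id < -999:
            raise ValueError(
                f"residue number {r.seq_id} does not fit the PDB fixed-column format"
            )
    st = gemmi.Structure()
    st.name = structure.id or "XXXX"
    model = gemmi.Model("1")
    for cid, residues in structure.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = r.name
            gr.seqid = gemmi.SeqId(r.seq_id, r.insertion_code or " ")
            gr.het_flag = "H" if r.het else "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = a.occupancy
                ga.b_iso = a.bfactor
                gr.add_atom(ga)
            chain.add_residue(gr)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def transform_structure(structure: Structure, rotation: np.ndarray,
                        translation: np.ndarray) -> Structure:
    """Return a copy with every atom position mapped to ``R x + t``."""
    out = structure.copy()
    R = np.asarray(rotation, float)
    t = np.asarray(translation, float)
    for _c, _r, a in out.iter_atoms():
        a.pos = R @ a.pos + t
    return out
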