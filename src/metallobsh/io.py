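"""File-format I/O: protein FASTA, read FASTQ/FASTA, PDB coordinates, TSV tables.

Thin wrappers over Biopython's parsers that return the package's own record
types. Record ids are the first whitespace-delimited token of the header.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import ProteinRecord
from .errors import InvalidInputError

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class ReadRecord:
    """A nucleotide sequencing read (alphabet ACGTN, optional quality string)."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise InvalidInputError(f"empty read {self.id!r}")
        bad = set(self.seq.upper()) - NUCLEOTIDE_ALPHABET
        if bad:
            raise InvalidInputError(
                f"read {self.id!r} contains non-nucleotide characters: {sorted(bad)}"
            )
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise InvalidInputError(f"read {self.id!r}: quality length != sequence length")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein sequences from FASTA."""
    return [ProteinRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein FASTA wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_reads(path: str | Path, fmt: str | None = None) -> list[ReadRecord]:
    """Read nucleotide reads from FASTQ or FASTA (inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        qual = None
        if fmt == "fastq":
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(ReadRecord(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        qual = r.qual or "I" * len(r.seq)
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


class PdbAtom(NamedTuple):
    chain: str
    element: str
    x: float
    y: float
    z: float


def read_pdb_atoms(path: str | Path) -> list[PdbAtom]:
    """All ATOM/HETATM coordinates of the first model of a PDB file."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    atoms = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                x, y, z = atom.coord
                atoms.append(
                    PdbAtom(chain.id, (atom.element or "").upper(), float(x), float(y), float(z))
                )
    return atoms
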