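"""Pairwise protein alignment primitives.

Global (Needleman-Wunsch) and local (Smith-Waterman) alignment with affine
gap penalties and substitution-matrix scoring, plus percent-identity
computation. These primitives back both the family-curation stage (all-vs-all
similarity networks, residue-conservation checks) and the translated read
search.

Conventions
-----------
* A gap of length ``L`` costs ``gap_open + L * gap_extend``.
* Percent identity is, by default, ``100 * n_identical / alignment_columns``
  with gap columns included in the denominator; ``denominator="shorter"``
  divides by the length of the shorter input instead.
* ``X`` (unknown residue) scores 0 against everything and never counts as an
  identity; the same holds for the stop symbol ``*`` appearing in translated
  reading frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InvalidAlphabetError, InvalidInputError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(STANDARD_AA + "X")
#: residues that never count toward identity (unknown residue, stop codon)
AMBIGUOUS = frozenset("X*")

DEFAULT_GLOBAL_PARAMS = {"gap_open": 10.0, "gap_extend": 0.5}
DEFAULT_LOCAL_PARAMS = {"gap_open": 11.0, "gap_extend": 1.0}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an accession-like identifier.

    The alphabet is the 20 standard amino acids plus ``X``.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise InvalidInputError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - PROTEIN_ALPHABET
        if bad:
            raise InvalidAlphabetError(
                f"record {self.id!r} contains non-amino-acid characters: {sorted(bad)}"
            )

    @property
    def length_aa(self) -> int:
        return len(self.seq)


class SubstitutionMatrix:
    """Symmetric residue-pair scoring matrix (BLOSUM62 by default).

    Wraps a :mod:`Bio.Align` substitution array. The unknown residue ``X`` is
    rescored to 0 against every residue, reflecting that an unknown position
    carries no evidence for or against homology.
    """

    def __init__(self, name: str = "BLOSUM62", zero_x: bool = True):
        self.name = name
        arr = substitution_matrices.load(name).copy()
        if zero_x and "X" in arr.alphabet:
            for ch in arr.alphabet:
                arr["X", ch] = 0.0
                arr[ch, "X"] = 0.0
        self._array = arr

    @property
    def alphabet(self) -> str:
        return str(self._array.alphabet)

    def score(self, a: str, b: str) -> float:
        return float(self._array[a, b])

    @property
    def array(self):
        return self._array


_DEFAULT_MATRIX: SubstitutionMatrix | None = None


def default_matrix() -> SubstitutionMatrix:
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = SubstitutionMatrix("BLOSUM62")
    return _DEFAULT_MATRIX


@dataclass
class AlignmentResult:
    """Outcome of a pairwise alignment.

    ``coords`` are 1-based inclusive ``(start_a, end_a, start_b, end_b)``
    positions of the aligned region on each input; for an empty local
    alignment all four are 0.
    """

    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    aln_len: int
    identity_pct: float
    mode: Literal["global", "local"]
    coords: tuple[int, int, int, int] = field(default=(0, 0, 0, 0))


def count_identities(aligned_a: str, aligned_b: str) -> int:
    """Number of identity columns; gap, ``X`` and ``*`` columns never count."""
    return sum(
        1
        for x, y in zip(aligned_a, aligned_b)
        if x == y and x != "-" and x not in AMBIGUOUS
    )


def _make_aligner(
    mode: str, matrix: SubstitutionMatrix, gap_open: float, gap_extend: float
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix.array
    # first gapped residue costs open+extend, each further residue costs extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _validate(seq: str, label: str, extra: str = "") -> None:
    if not seq:
        raise InvalidInputError(f"empty sequence for {label}")
    allowed = PROTEIN_ALPHABET | set(extra)
    bad = set(seq) - allowed
    if bad:
        raise InvalidAlphabetError(f"{label} contains invalid characters: {sorted(bad)}")


def _identity_denominator(aln_len: int, len_a: int, len_b: int, denominator: str) -> int:
    if denominator == "columns":
        return aln_len
    if denominator == "shorter":
        return min(len_a, len_b)
    raise InvalidInputError(f"unknown identity denominator {denominator!r}")


def _result_from_biopython(aln, mode: str, denominator: str, len_a: int, len_b: int) -> AlignmentResult:
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    aln_len = len(aligned_a)
    n_ident = count_identities(aligned_a, aligned_b)
    denom = _identity_denominator(aln_len, len_a, len_b, denominator)
    identity = 100.0 * n_ident / denom if denom else 0.0
    coords = aln.coordinates
    c = (int(coords[0][0]) + 1, int(coords[0][-1]), int(coords[1][0]) + 1, int(coords[1][-1]))
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        n_identical=n_ident,
        aln_len=aln_len,
        identity_pct=identity,
        mode=mode,  # type: ignore[arg-type]
        coords=c,
    )


def align_strings(
    a: str,
    b: str,
    mode: Literal["global", "local"] = "global",
    matrix: SubstitutionMatrix | None = None,
    gap_open: float | None = None,
    gap_extend: float | None = None,
    denominator: str = "columns",
) -> AlignmentResult:
    """Align two raw residue strings (may include ``*`` from translation)."""
    _validate(a, "sequence a", extra="*")
    _validate(b, "sequence b", extra="*")
    matrix = matrix or default_matrix()
    defaults = DEFAULT_GLOBAL_PARAMS if mode == "global" else DEFAULT_LOCAL_PARAMS
    go = defaults["gap_open"] if gap_open is None else gap_open
    ge = defaults["gap_extend"] if gap_extend is None else gap_extend
    aligner = _make_aligner(mode, matrix, go, ge)
    if mode == "local" and aligner.score(a, b) <= 0:
        return AlignmentResult("", "", 0.0, 0, 0, 0.0, "local")
    aln = aligner.align(a, b)[0]
    return _result_from_biopython(aln, mode, denominator, len(a), len(b))


def global_align(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float | None = None,
    gap_extend: float | None = None,
    denominator: str = "columns",
) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch) alignment under affine gaps."""
    return align_strings(
        a.seq, b.seq, "global", matrix, gap_open, gap_extend, denominator
    )


def local_align(
    query: ProteinRecord,
    target: ProteinRecord,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float | None = None,
    gap_extend: float | None = None,
    denominator: str = "columns",
) -> AlignmentResult:
    """Optimal local (Smith-Waterman) alignment; score is never negative."""
    return align_strings(
        query.seq, target.seq, "local", matrix, gap_open, gap_extend, denominator
    )


def percent_identity(a: ProteinRecord, b: ProteinRecord, **kwargs) -> float:
    """Global percent identity between two protein records."""
    return global_align(a, b, **kwargs).identity_pct
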