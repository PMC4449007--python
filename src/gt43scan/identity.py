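"""Pairwise protein alignment and percent amino-acid identity.

Global (Needleman-Wunsch with affine gaps, Gotoh) and local
(Smith-Waterman) protein alignment via Biopython's PairwiseAligner, with
BLOSUM62 scoring by default (gap open 10, extend 0.5).  Percent identity
supports the three common denominators — alignment columns, shorter
sequence length, and aligned (gap-free) residue pairs — with terminal-gap
columns excluded by default under the column convention, since published
identity figures for fragmentary peptides are typically computed over the
aligned core.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5

_DENOMINATORS = ("columns", "shorter_seq", "aligned_pairs")


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment as two gapped strings of equal length."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        if any(x == "-" and y == "-" for x, y in zip(self.aligned_a,
                                                     self.aligned_b)):
            raise ValueError("column with gaps in both rows")

    @property
    def identities(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-"
        )

    @property
    def aligned_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def aligned_pairs(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b)
            if x != "-" and y != "-"
        )


def _make_aligner(
    matrix: str, gap_open: float, gap_extend: float, mode: str
) -> Align.PairwiseAligner:
    try:
        sub = substitution_matrices.load(matrix)
    except FileNotFoundError:
        raise ValueError(
            f"unknown substitution matrix {matrix!r}; available: "
            f"{', '.join(substitution_matrices.load())}"
        )
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = sub
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aligner.mode = mode
    return aligner


def _align(
    a: str, b: str, matrix: str, gap_open: float, gap_extend: float, mode: str
) -> Alignment:
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper().rstrip("*"), b.upper().rstrip("*")
    aligner = _make_aligner(matrix, gap_open, gap_extend, mode)
    aln = aligner.align(a, b)[0]  # deterministic first traceback
    return Alignment(str(aln[0]), str(aln[1]), float(aln.score))


def global_align(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Optimal global alignment (affine gaps, end gaps penalized)."""
    return _align(a, b, matrix, gap_open, gap_extend, "global")


def local_align(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Optimal local (Smith-Waterman) alignment."""
    return _align(a, b, matrix, gap_open, gap_extend, "local")


def _trim_terminal_gap_columns(aln: Alignment) -> Alignment:
    """Drop leading/trailing columns that are gapped in either row."""
    a, b = aln.aligned_a, aln.aligned_b
    lo, hi = 0, len(a)
    while lo < hi and (a[lo] == "-" or b[lo] == "-"):
        lo += 1
    while hi > lo and (a[hi - 1] == "-" or b[hi - 1] == "-"):
        hi -= 1
    return Alignment(a[lo:hi], b[lo:hi], aln.score)


def percent_identity(
    aln: Alignment,
    denominator: str = "columns",
    trim_terminal_gaps: bool = True,
) -> float:
    """Percent identity of an alignment.

    denominator:
      * ``columns`` — alignment columns (terminal-gap columns excluded by
        default);
      * ``shorter_seq`` — length of the shorter input sequence;
      * ``aligned_pairs`` — gap-free columns only.
    """
    if denominator not in _DENOMINATORS:
        raise ValueError(f"denominator must be one of {_DENOMINATORS}")
    core = _trim_terminal_gaps_if(aln, trim_terminal_gaps, denominator)
    identities = core.identities
    if denominator == "columns":
        denom = core.aligned_columns
    elif denominator == "aligned_pairs":
        denom = core.aligned_pairs
    else:
        len_a = len(aln.aligned_a.replace("-", ""))
        len_b = len(aln.aligned_b.replace("-", ""))
        denom = min(len_a, len_b)
    if denom == 0:
        raise ValueError("zero-length denominator; identity undefined")
    return 100.0 * identities / denom


def _trim_terminal_gaps_if(aln, trim: bool, denominator: str) -> Alignment:
    if trim and denominator in ("columns", "aligned_pairs"):
        return _trim_terminal_gap_columns(aln)
    return aln
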