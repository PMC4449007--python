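"""Peptide extraction and filtering from assembled transcripts.

Downstream of read assembly, candidate GT43 peptides are mined from
transcripts by translating all six reading frames, extracting maximal
stop-to-stop open reading frames (no start-codon requirement, since
assembled transcripts are frequently 5'-truncated), keeping peptides longer
than a length cutoff (default: strictly more than 100 aa), and finally
requiring two independent lines of homology evidence, each at E-value
below 1e-10: a protein-database best hit and a GT43 domain hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

VALID_NT = frozenset("ACGTN")

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideCandidate:
    """One ORF: peptide plus its forward-strand nucleotide coordinates."""

    transcript_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    orf_start: int  # 1-based, on the forward strand, start <= end
    orf_end: int
    peptide: str

    @property
    def candidate_id(self) -> str:
        sign = "+" if self.frame > 0 else ""
        return (
            f"{self.transcript_id}|{sign}{self.frame}|"
            f"{self.orf_start}-{self.orf_end}"
        )


def _check_nucleotides(seq: str) -> str:
    seq = seq.strip().upper()
    for i, ch in enumerate(seq):
        if ch not in VALID_NT:
            raise ValueError(f"position {i + 1}: invalid nucleotide {ch!r}")
    return seq


def six_frame_translate(
    transcript: TranscriptRecord, table: int = 1
) -> dict[int, str]:
    """Translate all six frames with the given NCBI genetic-code table.

    Frames -1..-3 translate the reverse complement; codons containing N
    yield ``X`` (or ``*``/residue when the ambiguity is inconsequential,
    as Biopython resolves).  Trailing partial codons are dropped.
    """
    seq = _check_nucleotides(transcript.sequence)
    rc = str(Seq(seq).reverse_complement())
    frames: dict[int, str] = {}
    for f in (1, 2, 3):
        frames[f] = _translate_frame(seq[f - 1:], table)
        frames[-f] = _translate_frame(rc[f - 1:], table)
    return frames


def _translate_frame(sub: str, table: int) -> str:
    sub = sub[: len(sub) - len(sub) % 3]
    aa = list(str(Seq(sub).translate(table=table)))
    # any codon containing N is reported as X, even when every resolution
    # of the ambiguity encodes the same residue
    for i in range(len(aa)):
        if "N" in sub[3 * i:3 * i + 3]:
            aa[i] = "X"
    return "".join(aa)


def _orf_nt_coords(
    frame: int, aa_start0: int, aa_len: int, transcript_len: int
) -> tuple[int, int]:
    """Forward-strand 1-based nucleotide span of an ORF found at 0-based
    amino-acid offset ``aa_start0`` in the given frame's translation."""
    offset = abs(frame) - 1
    nt_from_5p = offset + 3 * aa_start0  # 0-based on the read strand
    nt_len = 3 * aa_len
    if frame > 0:
        start = nt_from_5p + 1
        return start, start + nt_len - 1
    # reverse strand: position 0 on the read strand is transcript_len on
    # the forward strand
    end = transcript_len - nt_from_5p
    return end - nt_len + 1, end


def extract_orfs(
    transcript: TranscriptRecord,
    min_len: int = 100,
    table: int = 1,
) -> list[PeptideCandidate]:
    """Maximal stop-to-stop ORFs longer than ``min_len`` amino acids.

    The length filter is strict: a peptide of exactly ``min_len`` residues
    is excluded.  ORFs are reported frame by frame (+1,+2,+3,-1,-2,-3),
    ordered within a frame by position.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    frames = six_frame_translate(transcript, table)
    out: list[PeptideCandidate] = []
    for frame in FRAMES:
        aa = frames[frame]
        pos = 0
        for chunk in aa.split("*"):
            if len(chunk) > min_len:
                start, end = _orf_nt_coords(
                    frame, pos, len(chunk), transcript.length
                )
                out.append(
                    PeptideCandidate(
                        transcript.transcript_id, frame, start, end, chunk
                    )
                )
            pos += len(chunk) + 1
    return out


def filter_candidates(
    candidates: Sequence[PeptideCandidate],
    domain_evalues: Mapping[str, float],
    blast_evalues: Mapping[str, float],
    cutoff: float = 1e-10,
) -> list[PeptideCandidate]:
    """Keep candidates passing BOTH homology filters at the cutoff.

    Evidence maps are keyed by :attr:`PeptideCandidate.candidate_id`; a
    candidate missing from either map is dropped.
    """
    kept = []
    for c in candidates:
        dom = domain_evalues.get(c.candidate_id)
        bla = blast_evalues.get(c.candidate_id)
        if dom is not None and bla is not None and dom < cutoff and bla < cutoff:
            kept.append(c)
    return kept
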