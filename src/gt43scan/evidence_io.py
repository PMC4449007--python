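"""Readers and writers for the pipeline's standard evidence files.

Formats handled:

* protein/nucleotide FASTA (via Biopython's SeqIO);
* HMMER3 per-domain tables (``--domtblout``), hmmsearch direction: the
  target column holds the protein, the query column the profile HMM;
* BLAST tabular output (``-outfmt 6``, the default 12 columns);
* two-column accession-to-CAZy-family maps (TSV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinRecord:
    seq_id: str
    description: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """Best profile-HMM evidence for one protein against one model."""

    query_id: str
    model_name: str
    full_seq_evalue: float
    best_domain_ievalue: float


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    rank_in_file: int


@dataclass(frozen=True)
class EvidenceRecord:
    """Per-protein homology evidence feeding the classifier."""

    query_id: str
    domain_evalue: float | None = None
    best_hit: BlastHit | None = None
    best_hit_family: str | None = None


def read_fasta(path: str | Path, allow_empty: bool = False) -> list[ProteinRecord]:
    """Read a FASTA file; IDs must be unique and sequences non-empty.

    A trailing ``*`` (stop) is stripped from each sequence.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).strip().upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {rec.id!r} in {path}")
        desc = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(rec.id, desc, seq))
    if not records and not allow_empty:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records wrapped at 60 columns."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.seq_id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


# domtblout columns (hmmsearch): 0 target, 3 query/model, 6 full-seq E-value,
# 12 i-Evalue; 22 data columns before the free-text description.
_DOMTBL_MIN_COLS = 22


def parse_domtbl(
    path: str | Path, model_name: str, evalue_field: str = "domain"
) -> list[DomainHit]:
    """Parse a HMMER3 per-domain table, one :class:`DomainHit` per protein.

    For each protein the minimum i-Evalue across its domain rows for the
    named model is kept (``evalue_field="full"`` keeps the full-sequence
    E-value instead for the comparison value, but both are recorded).
    """
    if evalue_field not in ("domain", "full"):
        raise ValueError("evalue_field must be 'domain' or 'full'")
    best: dict[str, tuple[float, float]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _DOMTBL_MIN_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_COLS} columns, "
                    f"got {len(cols)}"
                )
            target, model = cols[0], cols[3]
            if model != model_name:
                continue
            try:
                full_e = float(cols[6])
                dom_e = float(cols[12])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad E-value field: {exc}")
            if target not in best:
                order.append(target)
                best[target] = (full_e, dom_e)
            else:
                old_full, old_dom = best[target]
                best[target] = (min(old_full, full_e), min(old_dom, dom_e))
    return [
        DomainHit(q, model_name, best[q][0], best[q][1]) for q in order
    ]


def domain_evalue(hit: DomainHit, evalue_field: str = "domain") -> float:
    return hit.best_domain_ievalue if evalue_field == "domain" else hit.full_seq_evalue


def parse_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse BLAST ``-outfmt 6`` (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore)."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                hits.append(
                    BlastHit(cols[0], cols[1], float(cols[10]), float(cols[11]),
                             rank_in_file=len(hits))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad numeric field: {exc}")
    return hits


def best_hit(hits: Sequence[BlastHit]) -> BlastHit | None:
    """The most significant hit: minimum E-value, ties broken by maximum
    bitscore, then earliest position in the file."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h.evalue, -h.bitscore, h.rank_in_file))


def best_hits_per_query(hits: Iterable[BlastHit]) -> dict[str, BlastHit]:
    grouped: dict[str, list[BlastHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    return {q: best_hit(hs) for q, hs in grouped.items()}  # type: ignore[misc]


def load_family_map(path: str | Path) -> dict[str, str]:
    """Load a two-column accession→family TSV."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 2 or not cols[0] or not cols[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            mapping[cols[0]] = cols[1]
    return mapping


def annotate(
    query_id: str,
    domain_hit: DomainHit | None,
    blast_best: BlastHit | None,
    family_map: dict[str, str],
    evalue_field: str = "domain",
) -> EvidenceRecord:
    """Combine domain and BLAST evidence for one protein.

    Best hits whose accession is absent from the family map are labelled
    ``UNKNOWN`` with a warning, never dropped.
    """
    family = None
    if blast_best is not None:
        family = family_map.get(blast_best.subject_id)
        if family is None:
            logger.warning(
                "best hit %s for query %s not in family map; labelling UNKNOWN",
                blast_best.subject_id, query_id,
            )
            family = "UNKNOWN"
    return EvidenceRecord(
        query_id=query_id,
        domain_evalue=(
            domain_evalue(domain_hit, evalue_field) if domain_hit else None
        ),
        best_hit=blast_best,
        best_hit_family=family,
    )
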