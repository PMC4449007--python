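"""Multi-evidence classification cascade for GT43 candidacy.

Three lines of evidence are combined for each protein:

1. the GT43 profile-HMM domain E-value (strict cutoff 1e-10, relaxed 1e-5);
2. whether the best database hit belongs to CAZy family GT43;
3. the number of distinct signature motifs found in their allowed zones
   (at least 3 of 8 for confirmation).

Labels form a small lattice:

* ``CONFIRMED``    — strict domain E-value, GT43 best hit, >= min_motifs;
* ``CANDIDATE``    — strict domain E-value, GT43 best hit, too few motifs
  (typically short fragments);
* ``WEAK_HOMOLOG`` — domain E-value between the strict and relaxed cutoffs,
  any best-hit family (the band dominated by false positives);
* ``REJECTED``     — everything else, including strict-E-value proteins
  whose best database hit is a different family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import pandas as pd

from .evidence_io import EvidenceRecord
from .panel import MotifScanResult

GT43_FAMILY = "GT43"


class Label(str, Enum):
    CONFIRMED = "CONFIRMED"
    CANDIDATE = "CANDIDATE"
    WEAK_HOMOLOG = "WEAK_HOMOLOG"
    REJECTED = "REJECTED"


@dataclass(frozen=True)
class Thresholds:
    strict_cutoff: float = 1e-10
    relaxed_cutoff: float = 1e-5
    min_motifs: int = 3

    def __post_init__(self) -> None:
        if not (self.relaxed_cutoff > self.strict_cutoff > 0):
            raise ValueError("need relaxed_cutoff > strict_cutoff > 0")
        if not (0 <= self.min_motifs <= 8):
            raise ValueError("min_motifs must be between 0 and 8")


@dataclass(frozen=True)
class ClassificationResult:
    seq_id: str
    label: Label
    domain_evalue: float | None
    best_hit_family: str | None
    motif_count: int
    reasons: tuple[str, ...]


def classify(
    evidence: EvidenceRecord,
    scan: MotifScanResult,
    thresholds: Thresholds = Thresholds(),
    lenient_besthit: bool = False,
) -> ClassificationResult:
    """Assign one label from the evidence cascade.

    ``lenient_besthit=True`` downgrades strict-E-value proteins with a
    non-GT43 best hit to CANDIDATE instead of REJECTED.
    """
    if evidence.query_id != scan.seq_id:
        raise ValueError(
            f"evidence is for {evidence.query_id!r} but scan is for "
            f"{scan.seq_id!r}"
        )
    t = thresholds
    e = evidence.domain_evalue
    family = evidence.best_hit_family
    n = scan.motif_count
    reasons: list[str] = []

    if e is None:
        reasons.append("no domain hit")
        label = Label.REJECTED
    elif e < t.strict_cutoff:
        reasons.append(f"domain E-value {e:.3g} < strict cutoff {t.strict_cutoff:g}")
        if family == GT43_FAMILY:
            reasons.append(f"best hit family {GT43_FAMILY}")
            if n >= t.min_motifs:
                reasons.append(f"motif count {n} >= {t.min_motifs}")
                label = Label.CONFIRMED
            else:
                reasons.append(f"motif count {n} < {t.min_motifs}")
                label = Label.CANDIDATE
        else:
            reasons.append(f"best hit family {family or 'absent'} != {GT43_FAMILY}")
            label = Label.CANDIDATE if lenient_besthit else Label.REJECTED
    elif e < t.relaxed_cutoff:
        reasons.append(
            f"domain E-value {e:.3g} in relaxed band "
            f"[{t.strict_cutoff:g}, {t.relaxed_cutoff:g})"
        )
        label = Label.WEAK_HOMOLOG
    else:
        reasons.append(
            f"domain E-value {e:.3g} >= relaxed cutoff {t.relaxed_cutoff:g}"
        )
        label = Label.REJECTED

    return ClassificationResult(
        seq_id=evidence.query_id,
        label=label,
        domain_evalue=e,
        best_hit_family=family,
        motif_count=n,
        reasons=tuple(reasons),
    )


def results_table(
    results: Sequence[ClassificationResult],
    lengths: dict[str, int] | None = None,
    descriptions: dict[str, str] | None = None,
    best_hits: dict[str, tuple[str, float]] | None = None,
) -> pd.DataFrame:
    """Tabulate results, ordered by descending motif count then ascending
    domain E-value (strongest evidence first), id as final tie-break."""
    rows = []
    for r in results:
        bh = (best_hits or {}).get(r.seq_id)
        rows.append(
            {
                "seq_id": r.seq_id,
                "length": (lengths or {}).get(r.seq_id),
                "description": (descriptions or {}).get(r.seq_id, ""),
                "domain_evalue": r.domain_evalue,
                "best_hit": bh[0] if bh else None,
                "best_hit_evalue": bh[1] if bh else None,
                "best_hit_family": r.best_hit_family,
                "motif_count": r.motif_count,
                "label": r.label.value,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "seq_id", "length", "description", "domain_evalue", "best_hit",
            "best_hit_evalue", "best_hit_family", "motif_count", "label",
        ],
    )
    if df.empty:
        return df
    df["_e"] = df["domain_evalue"].fillna(float("inf"))
    df = (
        df.sort_values(
            ["motif_count", "_e", "seq_id"], ascending=[False, True, True]
        )
        .drop(columns="_e")
        .reset_index(drop=True)
    )
    return df


def run_pipeline(
    fasta_path,
    domtbl_path,
    blast_path,
    family_map_path,
    thresholds: Thresholds = Thresholds(),
    panel=None,
    model_name: str = "GT43",
    evalue_field: str = "domain",
    middle_frac: float = 0.5,
    lenient_besthit: bool = False,
) -> tuple[list[ClassificationResult], pd.DataFrame, dict[str, int]]:
    """Classify every protein in a FASTA file from its evidence files.

    Proteins with no domain-table row are still classified (REJECTED with
    reason "no domain hit").  Returns the per-protein results, the ordered
    report table and a per-label summary.
    """
    from . import evidence_io as eio
    from .panel import scan_protein

    proteins = eio.read_fasta(fasta_path, allow_empty=True)
    dom_hits = {
        h.query_id: h for h in eio.parse_domtbl(domtbl_path, model_name,
                                                evalue_field)
    }
    blast_best = eio.best_hits_per_query(eio.parse_blast_tab(blast_path))
    fam_map = eio.load_family_map(family_map_path)

    results: list[ClassificationResult] = []
    best_hits: dict[str, tuple[str, float]] = {}
    for prot in proteins:
        evidence = eio.annotate(
            prot.seq_id, dom_hits.get(prot.seq_id),
            blast_best.get(prot.seq_id), fam_map, evalue_field,
        )
        scan = scan_protein(prot.seq_id, prot.sequence, panel, middle_frac)
        results.append(classify(evidence, scan, thresholds, lenient_besthit))
        if evidence.best_hit is not None:
            best_hits[prot.seq_id] = (
                evidence.best_hit.subject_id, evidence.best_hit.evalue
            )

    report = results_table(
        results,
        lengths={p.seq_id: p.length for p in proteins},
        descriptions={p.seq_id: p.description for p in proteins},
        best_hits=best_hits,
    )
    return results, report, summarize(results)


def summarize(results: Sequence[ClassificationResult]) -> dict[str, int]:
    counts = {label.value: 0 for label in Label}
    for r in results:
        counts[r.label.value] += 1
    counts["total"] = len(results)
    return counts
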