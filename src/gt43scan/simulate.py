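"""Synthetic sequences and evidence files with exact planted ground truth.

Every stage of the pipeline can be exercised without downloads:

* proteins with panel motifs planted at controlled positions on a
  rejection-sampled background certified to contain no accidental panel
  match, so the true motif count is known exactly;
* motif-free decoy proteins (same certification);
* transcripts back-translated from peptides with stop-delimited flanks so
  the maximal ORF is exactly the source peptide;
* mock HMMER domain tables, BLAST tabular files and family maps consistent
  with the planted truth: positives carry highly significant GT43 evidence
  (domain E-values log-uniform in [1e-60, 1e-11], GT43-family best hit),
  decoys fall in the weak band ([1e-9, 1e-6], GT2-family best hit) or have
  no hit at all, mirroring the false-positive band seen in real searches.

All outputs are deterministic given (seed, parameters).
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .evidence_io import ProteinRecord, write_fasta
from .mining import TranscriptRecord
from .panel import (
    MotifDefinition,
    Zone,
    default_panel,
    zone_interval,
)
from .prosite import ElementKind, PrositePattern, find_matches

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: approximate Swiss-Prot residue composition, an optional background
SWISSPROT_FREQS = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

MAX_REJECTION_ATTEMPTS = 1000

#: standard-code codons per amino acid (for back-translation)
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_STOPS = ["TAA", "TAG", "TGA"]

IN_ZONE = "IN_ZONE"
OUT_OF_ZONE = "OUT_OF_ZONE"


@dataclass(frozen=True)
class PlantSpec:
    """Request to plant one motif: a fixed start, or a zone directive."""

    motif_id: int
    target_start: int | str  # 1-based position, IN_ZONE or OUT_OF_ZONE


@dataclass(frozen=True)
class PlantedMotif:
    motif_id: int
    start: int
    realization: str
    in_zone: bool


@dataclass(frozen=True)
class TruthRecord:
    seq_id: str
    planted: tuple[PlantedMotif, ...]
    is_decoy: bool

    @property
    def expected_motif_count(self) -> int:
        return len({p.motif_id for p in self.planted if p.in_zone})


def _pattern_language(pattern: PrositePattern) -> list[str]:
    """All strings matching a repeat-free literal/class pattern."""
    choices = []
    for e in pattern.elements:
        if e.kind not in (ElementKind.LITERAL, ElementKind.CLASS) or (
            e.min_repeat, e.max_repeat
        ) != (1, 1):
            raise ValueError(
                "motif realization requires literal/class elements without "
                "repeats"
            )
        choices.append(sorted(e.residues))
    return ["".join(p) for p in itertools.product(*choices)]


def realize_motif(
    motif: MotifDefinition, rng: np.random.Generator
) -> str:
    """Draw uniformly from the motif pattern's finite language."""
    lang = _pattern_language(motif.pattern)
    return lang[int(rng.integers(len(lang)))]


def _resolve_start(
    spec: PlantSpec,
    motif: MotifDefinition,
    realization: str,
    length: int,
    rng: np.random.Generator,
    middle_frac: float,
    taken: list[tuple[int, int]],
) -> int:
    span = len(realization)
    if isinstance(spec.target_start, int):
        candidates = [spec.target_start]
    else:
        lo, hi = zone_interval(motif.zone, length, middle_frac)
        allowed = set(range(lo, min(hi, length - span + 1) + 1))
        if spec.target_start == OUT_OF_ZONE:
            allowed = set(range(1, length - span + 2)) - allowed
        ordered = sorted(allowed)
        candidates = [ordered[i] for i in rng.permutation(len(ordered))]
    for start in candidates:
        end = start + span - 1
        if end > length or start < 1:
            continue
        if all(end < s or start > e for s, e in taken):
            return start
    raise ValueError(
        f"cannot place motif {spec.motif_id} ({spec.target_start}); "
        "sequence too short or plants overlap"
    )


def generate_protein(
    seed: int,
    length: int,
    plants: Sequence[PlantSpec],
    seq_id: str = "synth",
    background: dict[str, float] | None = None,
    panel: Sequence[MotifDefinition] | None = None,
    middle_frac: float = 0.5,
) -> tuple[ProteinRecord, TruthRecord]:
    """A protein with exactly the requested panel-motif content.

    Background residues are i.i.d. from ``background`` (uniform over the 20
    standard residues by default); the whole construct is rejection-sampled
    until the only panel matches anywhere in the sequence are the planted
    ones, so the truth record is exact.  Decoys (no plants) are therefore
    certified motif-free.
    """
    rng = np.random.default_rng(seed)
    if panel is None:
        panel = default_panel()
    by_id = {m.motif_id: m for m in panel}
    for spec in plants:
        if spec.motif_id not in by_id:
            raise ValueError(f"unknown motif_id {spec.motif_id}")

    if background is None:
        letters, probs = list(AA20), None
    else:
        letters = sorted(background)
        total = sum(background.values())
        probs = [background[k] / total for k in letters]

    for _attempt in range(MAX_REJECTION_ATTEMPTS):
        planted: list[PlantedMotif] = []
        taken: list[tuple[int, int]] = []
        ok = True
        for spec in plants:
            motif = by_id[spec.motif_id]
            realization = realize_motif(motif, rng)
            try:
                start = _resolve_start(
                    spec, motif, realization, length, rng, middle_frac, taken
                )
            except ValueError:
                if isinstance(spec.target_start, int):
                    raise
                ok = False
                break
            lo, hi = zone_interval(motif.zone, length, middle_frac)
            taken.append((start, start + len(realization) - 1))
            planted.append(
                PlantedMotif(spec.motif_id, start, realization,
                             lo <= start <= hi)
            )
        if not ok:
            continue

        residues = rng.choice(letters, size=length, p=probs)
        seq = list("".join(residues))
        for p in planted:
            seq[p.start - 1:p.start - 1 + len(p.realization)] = p.realization
        sequence = "".join(seq)

        if _only_planted_matches(sequence, panel, planted):
            return (
                ProteinRecord(seq_id, "synthetic", sequence),
                TruthRecord(seq_id, tuple(planted), is_decoy=not plants),
            )
    raise RuntimeError(
        f"rejection sampling failed after {MAX_REJECTION_ATTEMPTS} attempts; "
        "try a longer sequence or fewer plants"
    )


def _only_planted_matches(
    sequence: str,
    panel: Sequence[MotifDefinition],
    planted: Sequence[PlantedMotif],
) -> bool:
    wanted = {(p.motif_id, p.start) for p in planted}
    found: set[tuple[int, int]] = set()
    for motif in panel:
        for span in find_matches(motif.pattern, sequence):
            found.add((motif.motif_id, span.start))
    return found == wanted


def generate_transcript(
    peptide: str,
    seed: int,
    flank_lengths: tuple[int, int] = (30, 30),
    transcript_id: str = "synth_t",
) -> TranscriptRecord:
    """Back-translate a peptide into a transcript whose frame +1 maximal
    ORF is exactly the peptide.

    Codons are drawn uniformly among synonyms.  Flanks are random but
    bracketed by in-frame stop codons (5' flank ends with a stop; the coding
    region is followed by a stop), so stop-to-stop ORF extraction recovers
    the peptide exactly.  Flank lengths are rounded up to codon multiples.
    """
    peptide = peptide.strip().upper()
    if not peptide or "*" in peptide:
        raise ValueError("peptide must be non-empty and stop-free")
    rng = np.random.default_rng(seed)

    def random_codons(n: int) -> str:
        return "".join(
            _CODONS[AA20[int(i)]][0] for i in rng.integers(0, 20, size=n)
        )

    coding = "".join(
        _CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in peptide
    )
    stop = _STOPS[int(rng.integers(3))]

    up_codons = max(1, -(-flank_lengths[0] // 3)) if flank_lengths[0] else 0
    down_codons = max(1, -(-flank_lengths[1] // 3)) if flank_lengths[1] else 0
    upstream = (
        random_codons(up_codons - 1) + _STOPS[int(rng.integers(3))]
        if up_codons else ""
    )
    downstream = random_codons(down_codons) if down_codons else ""
    return TranscriptRecord(transcript_id, upstream + coding + stop + downstream)


def generate_mock_evidence(
    truths: Sequence[TruthRecord],
    seed: int,
    outdir: str | Path,
    model_name: str = "GT43",
    decoy_hit_prob: float = 0.5,
) -> tuple[Path, Path, Path]:
    """Write mock domtbl / BLAST / family-map files consistent with truth.

    Positives (non-decoys) draw domain E-values log-uniformly from
    [1e-60, 1e-11] and hit a GT43 reference accession; decoys either lack
    evidence entirely or draw from the weak band [1e-9, 1e-6] with a GT2
    best hit.  Returns the three file paths.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    domtbl = outdir / "mock.domtbl"
    blast = outdir / "mock.blast.tsv"
    fam = outdir / "family_map.tsv"

    gt43_refs = [f"GT43REF{i:03d}.1" for i in range(1, 6)]
    gt2_refs = [f"GT2REF{i:03d}.1" for i in range(1, 4)]

    dom_rows: list[str] = []
    blast_rows: list[str] = []
    for t in truths:
        if not t.is_decoy:
            log_e = rng.uniform(-60, -11)
            subject = gt43_refs[int(rng.integers(len(gt43_refs)))]
            blast_e = 10.0 ** rng.uniform(-50, -12)
        elif rng.random() < decoy_hit_prob:
            log_e = rng.uniform(-9, -6)
            subject = gt2_refs[int(rng.integers(len(gt2_refs)))]
            blast_e = 10.0 ** rng.uniform(-8, -4)
        else:
            continue
        evalue = 10.0 ** log_e
        score = max(5.0, -log_e * 3.0)
        dom_rows.append(
            f"{t.seq_id} - 400 {model_name} - 250 {evalue:.3g} {score:.1f} 0.1 "
            f"1 1 {evalue:.3g} {evalue:.3g} {score:.1f} 0.1 "
            f"1 250 10 260 5 270 0.95 -"
        )
        bits = max(30.0, score * 2)
        blast_rows.append(
            "\t".join([
                t.seq_id, subject, "45.0", "200", "110", "3", "1", "200",
                "1", "200", f"{blast_e:.3g}", f"{bits:.1f}",
            ])
        )

    with open(domtbl, "w") as fh:
        fh.write("# mock HMMER3 per-domain output (synthetic)\n")
        fh.write("#\n")
        for row in dom_rows:
            fh.write(row + "\n")
    with open(blast, "w") as fh:
        fh.write("\n".join(blast_rows) + ("\n" if blast_rows else ""))
    with open(fam, "w") as fh:
        for acc in gt43_refs:
            fh.write(f"{acc}\tGT43\n")
        for acc in gt2_refs:
            fh.write(f"{acc}\tGT2\n")
    return domtbl, blast, fam


def write_truth(truths: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["seq_id", "is_decoy", "expected_motif_count", "planted"])
        for t in truths:
            planted = ";".join(
                f"{p.motif_id}@{p.start}:{'in' if p.in_zone else 'out'}"
                for p in t.planted
            )
            w.writerow([t.seq_id, int(t.is_decoy), t.expected_motif_count,
                        planted])


def simulate_dataset(
    n_positives: int,
    n_decoys: int,
    seed: int,
    outdir: str | Path,
    length_range: tuple[int, int] = (200, 500),
    motifs_per_positive: tuple[int, int] = (3, 8),
    middle_frac: float = 0.5,
) -> dict[str, Path]:
    """Generate a complete study: proteins, transcripts, truth, evidence.

    Positives carry between ``motifs_per_positive`` distinct in-zone motifs;
    decoys carry none.  Protein lengths are uniform in ``length_range``
    (default 200-500 aa, within the 100-600 aa range typical of GT43
    catalytic proteins).  Writes proteins.faa, transcripts.fna, truth.tsv,
    mock.domtbl, mock.blast.tsv and family_map.tsv into ``outdir``.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    proteins: list[ProteinRecord] = []
    truths: list[TruthRecord] = []
    for i in range(n_positives + n_decoys):
        is_pos = i < n_positives
        seq_id = f"{'POS' if is_pos else 'DEC'}{i:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if is_pos:
            k = int(rng.integers(motifs_per_positive[0],
                                 motifs_per_positive[1] + 1))
            ids = sorted(rng.choice(range(1, 9), size=k, replace=False))
            plants = [PlantSpec(int(m), IN_ZONE) for m in ids]
        else:
            plants = []
        rec, truth = generate_protein(
            int(rng.integers(2**31)), length, plants, seq_id,
            middle_frac=middle_frac,
        )
        proteins.append(rec)
        truths.append(truth)

    write_fasta(proteins, outdir / "proteins.faa")
    write_truth(truths, outdir / "truth.tsv")
    generate_mock_evidence(truths, int(rng.integers(2**31)), outdir)

    transcripts = [
        generate_transcript(
            p.sequence, int(rng.integers(2**31)),
            transcript_id=f"t_{p.seq_id}",
        )
        for p in proteins[: min(5, len(proteins))]
    ]
    with open(outdir / "transcripts.fna", "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id}\n")
            for i in range(0, len(t.sequence), 60):
                fh.write(t.sequence[i:i + 60] + "\n")

    return {
        "proteins": outdir / "proteins.faa",
        "transcripts": outdir / "transcripts.fna",
        "truth": outdir / "truth.tsv",
        "domtbl": outdir / "mock.domtbl",
        "blast": outdir / "mock.blast.tsv",
        "family_map": outdir / "family_map.tsv",
    }
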