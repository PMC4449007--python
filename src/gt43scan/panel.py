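"""The eight-motif GT43 signature panel with positional-zone constraints.

The panel captures substrate-interacting regions of human GlcAT-I
(beta-1,3-glucuronyltransferase I, UniProt O94766), the structurally solved
reference protein of CAZy family GT43.  Each motif is a strict PROSITE-style
pattern together with a zone rule restricting where along a candidate
protein the motif may occur:

* motifs 1-2 must start in the N-terminal half,
* motifs 7-8 must start in the C-terminal half,
* motifs 3-6 must start in the middle part (by default the central half).

A protein's motif count is the number of distinct motifs with at least one
zone-satisfying occurrence; counts of three or more are treated as strong
support for GT43 membership by the downstream classifier.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .prosite import MatchSpan, PrositePattern, find_matches, parse_pattern


class Zone(str, Enum):
    N_HALF = "N_HALF"
    MIDDLE = "MIDDLE"
    C_HALF = "C_HALF"


#: (motif_id, pattern, zone, reference start/end in human GlcAT-I)
_PANEL_SPEC: tuple[tuple[int, str, Zone, int, int], ...] = (
    (1, "T-P-[TI]-[YI]", Zone.N_HALF, 81, 84),
    (2, "W-[IL]-[ILV]-[VIA]-E-[DAKG]", Zone.N_HALF, 108, 113),
    (3, "[QMN]-R-[NL]", Zone.MIDDLE, 160, 162),
    (4, "D-D-[DS]-N", Zone.MIDDLE, 194, 197),
    (5, "[EQ]-[GA]-P", Zone.MIDDLE, 227, 229),
    (6, "[ILVM]-[DEH]-[MWI]-[AS]-[GS]-F", Zone.MIDDLE, 251, 256),
    (7, "[QLN]-[DE]-[SNT]", Zone.C_HALF, 280, 282),
    (8, "W-[HRNW]-[LT]-[RQKH]", Zone.C_HALF, 307, 310),
)

#: default fraction of the sequence length covered by the MIDDLE zone
DEFAULT_MIDDLE_FRAC = 0.5


@dataclass(frozen=True)
class MotifDefinition:
    """One panel motif: pattern, zone rule and GlcAT-I reference span."""

    motif_id: int
    pattern: PrositePattern
    zone: Zone
    glcat1_start: int
    glcat1_end: int


@dataclass(frozen=True)
class MotifHit:
    motif_id: int
    span: MatchSpan
    zone_ok: bool


@dataclass(frozen=True)
class MotifScanResult:
    """All panel hits for one protein plus the zone-filtered motif count."""

    seq_id: str
    seq_length: int
    hits: tuple[MotifHit, ...]
    motif_count: int

    def hits_for(self, motif_id: int) -> list[MotifHit]:
        return [h for h in self.hits if h.motif_id == motif_id]


def default_panel() -> list[MotifDefinition]:
    """The eight GT43 signature motifs in motif-id order."""
    return [
        MotifDefinition(mid, parse_pattern(pat), zone, s, e)
        for mid, pat, zone, s, e in _PANEL_SPEC
    ]


def zone_interval(
    zone: Zone, seq_length: int, middle_frac: float = DEFAULT_MIDDLE_FRAC
) -> tuple[int, int]:
    """1-based inclusive interval of allowed match START positions.

    Halves split at floor(L/2), the boundary residue belonging to the first
    half.  The middle zone is the centered window covering ``middle_frac``
    of the length: [floor(L*(1-f)/2)+1, floor(L*(1+f)/2)].
    """
    if seq_length < 1:
        raise ValueError("sequence length must be >= 1")
    if not (0 < middle_frac <= 1):
        raise ValueError("middle_frac must be in (0, 1]")
    half = seq_length // 2
    if zone is Zone.N_HALF:
        return 1, half
    if zone is Zone.C_HALF:
        return half + 1, seq_length
    eps = 1e-9  # guard against binary rounding of fractions like 0.8
    lo = math.floor(seq_length * (1 - middle_frac) / 2 + eps) + 1
    hi = math.floor(seq_length * (1 + middle_frac) / 2 + eps)
    return lo, hi


def scan_protein(
    seq_id: str,
    sequence: str,
    panel: Sequence[MotifDefinition] | None = None,
    middle_frac: float = DEFAULT_MIDDLE_FRAC,
) -> MotifScanResult:
    """Scan one protein against the panel.

    Every occurrence of every motif is reported with a zone flag; the motif
    count tallies distinct motifs having at least one in-zone occurrence.
    Zone membership is judged by the occurrence's start position only.
    """
    if panel is None:
        panel = default_panel()
    length = len(sequence.strip().rstrip("*"))
    hits: list[MotifHit] = []
    in_zone_ids: set[int] = set()
    for motif in panel:
        lo, hi = zone_interval(motif.zone, length, middle_frac)
        for span in find_matches(motif.pattern, sequence):
            ok = lo <= span.start <= hi
            hits.append(MotifHit(motif.motif_id, span, ok))
            if ok:
                in_zone_ids.add(motif.motif_id)
    return MotifScanResult(seq_id, length, tuple(hits), len(in_zone_ids))


def load_panel(path: str | Path) -> list[MotifDefinition]:
    """Read a custom panel from TSV (motif_id, pattern, zone, ref_start, ref_end)."""
    panel = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"motif_id", "pattern", "zone", "ref_start", "ref_end"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"panel file must have columns {sorted(required)}")
        for row in reader:
            panel.append(
                MotifDefinition(
                    int(row["motif_id"]),
                    parse_pattern(row["pattern"]),
                    Zone(row["zone"]),
                    int(row["ref_start"]),
                    int(row["ref_end"]),
                )
            )
    if not panel:
        raise ValueError("panel file contains no motifs")
    return panel


def write_panel(panel: Iterable[MotifDefinition], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["motif_id", "pattern", "zone", "ref_start", "ref_end"])
        for m in panel:
            writer.writerow(
                [m.motif_id, m.pattern.source_text, m.zone.value,
                 m.glcat1_start, m.glcat1_end]
            )
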