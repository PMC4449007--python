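"""Independent reference implementations used only by the test suite.

Each oracle takes a different route from the code under test: the pattern
oracle goes through Python's regex engine; the translation oracle does
manual codon chunking against Biopython's raw codon table; the alignment
oracle enumerates alignment paths exhaustively.
"""

from __future__ import annotations

import re
from functools import lru_cache

from Bio.Data.CodonTable import unambiguous_dna_by_id

from gt43scan.prosite import ElementKind, PrositePattern, VALID_SEQ_LETTERS


def _element_regex(elem) -> str:
    if elem.kind is ElementKind.ANY:
        core = "."
    elif elem.kind is ElementKind.LITERAL:
        core = re.escape(next(iter(elem.residues)))
    elif elem.kind is ElementKind.CLASS:
        core = "[" + "".join(sorted(elem.residues)) + "]"
    else:
        # X never satisfies a negated class (conservative ambiguity rule)
        excluded = set(elem.residues) | {"X"}
        core = "[^" + "".join(sorted(excluded)) + "]"
    if (elem.min_repeat, elem.max_repeat) == (1, 1):
        return f"(?:{core})"
    return f"(?:{core}){{{elem.min_repeat},{elem.max_repeat}}}"


def regex_find_matches(pattern: PrositePattern, sequence: str):
    """All (start, end) 1-based spans, via regex fullmatch on every window."""
    seq = sequence.upper().rstrip("*")
    rx = re.compile("".join(_element_regex(e) for e in pattern.elements))
    spans = []
    starts = [0] if pattern.anchored_start else range(len(seq))
    for s in starts:
        for length in range(pattern.min_span, pattern.max_span + 1):
            e = s + length
            if e > len(seq):
                break
            if pattern.anchored_end and e != len(seq):
                continue
            if rx.fullmatch(seq, s, e):
                spans.append((s + 1, e))
    return sorted(spans)


_TABLE = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE.forward_table)
_CODON_TO_AA.update({c: "*" for c in _TABLE.stop_codons})
_COMP = str.maketrans("ACGTN", "TGCAN")


def naive_translate(nt: str) -> str:
    out = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i:i + 3]
        out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def naive_six_frame_orfs(nt: str, min_len: int):
    """Brute-force stop-to-stop ORF peptides over all six frames."""
    nt = nt.upper()
    rc = nt.translate(_COMP)[::-1]
    peptides = []
    for strand in (nt, rc):
        for off in range(3):
            for chunk in naive_translate(strand[off:]).split("*"):
                if len(chunk) > min_len:
                    peptides.append(chunk)
    return sorted(peptides)


def brute_force_global_score(
    a: str, b: str, sub, gap_open: float, gap_extend: float
) -> float:
    """Maximum global alignment score by exhaustive path enumeration.

    A run of k consecutive gaps in one row costs gap_open + (k-1)*gap_extend
    (end gaps included), matching an affine-gap global aligner.  Exponential;
    intended for sequences of length <= 6.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(sub[a[i], b[j]] + best(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b
            cost = -gap_extend if last == "A" else -gap_open
            options.append(cost + best(i + 1, j, "A"))
        if j < len(b):  # gap in a
            cost = -gap_extend if last == "B" else -gap_open
            options.append(cost + best(i, j + 1, "B"))
        return max(options)

    return best(0, 0, "M")
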