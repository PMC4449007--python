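"""PROSITE-style pattern parsing and matching for protein sequences.

A PROSITE pattern is a dash-separated list of position elements:

* a literal residue, e.g. ``T``;
* a residue class in square brackets, e.g. ``[TI]`` (any of T or I);
* a negated class in curly braces, e.g. ``{P}`` (anything but P);
* the wildcard ``x`` (any residue);
* any element may carry a repeat count ``(n)`` or range ``(n,m)``;
* optional anchors ``<`` (N terminus) and ``>`` (C terminus).

Patterns here are deterministic: a position either matches a residue or it
does not, with no profile weights.  All (possibly overlapping) occurrences
are reported with 1-based inclusive coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: extra letters accepted in patterns/sequences when written explicitly
EXTENDED_AA = frozenset("BZXUO")
VALID_SEQ_LETTERS = STANDARD_AA | EXTENDED_AA


class PatternSyntaxError(ValueError):
    """Raised when a pattern string cannot be parsed.

    Carries ``element_index`` (1-based) of the offending dash-separated
    element.
    """

    def __init__(self, message: str, element_index: int):
        super().__init__(f"element {element_index}: {message}")
        self.element_index = element_index


class SequenceError(ValueError):
    """Raised when a protein sequence contains an invalid character."""

    def __init__(self, message: str, position: int):
        super().__init__(f"position {position}: {message}")
        self.position = position


class ElementKind(str, Enum):
    LITERAL = "literal"
    CLASS = "class"
    NEGATED_CLASS = "negated_class"
    ANY = "any"


@dataclass(frozen=True)
class PatternElement:
    """One position of a pattern, possibly repeated.

    ``residues`` is empty for the wildcard; a single letter for literals;
    the allowed (or excluded) set for classes.
    """

    kind: ElementKind
    residues: frozenset[str]
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if self.min_repeat < 1 or self.max_repeat < self.min_repeat:
            raise ValueError("invalid repeat counts")
        if self.kind is ElementKind.LITERAL and len(self.residues) != 1:
            raise ValueError("literal element must hold exactly one residue")

    def matches(self, residue: str) -> bool:
        """Whether a single upper-case residue satisfies this position.

        ``X`` in a sequence is treated conservatively: it satisfies only the
        wildcard or a class that explicitly lists X.
        """
        if self.kind is ElementKind.ANY:
            return True
        if residue == "X" and "X" not in self.residues:
            return False
        if self.kind is ElementKind.LITERAL or self.kind is ElementKind.CLASS:
            return residue in self.residues
        return residue not in self.residues  # negated class

    def render(self) -> str:
        if self.kind is ElementKind.ANY:
            core = "x"
        elif self.kind is ElementKind.LITERAL:
            core = next(iter(self.residues))
        else:
            inner = "".join(sorted(self.residues))
            core = f"[{inner}]" if self.kind is ElementKind.CLASS else f"{{{inner}}}"
        if (self.min_repeat, self.max_repeat) == (1, 1):
            return core
        if self.min_repeat == self.max_repeat:
            return f"{core}({self.min_repeat})"
        return f"{core}({self.min_repeat},{self.max_repeat})"


@dataclass(frozen=True)
class PrositePattern:
    """A parsed pattern: ordered elements plus anchoring flags."""

    source_text: str
    elements: tuple[PatternElement, ...]
    anchored_start: bool = False
    anchored_end: bool = False

    @property
    def min_span(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.max_repeat for e in self.elements)

    def render(self) -> str:
        body = "-".join(e.render() for e in self.elements)
        return ("<" if self.anchored_start else "") + body + (
            ">" if self.anchored_end else ""
        )


_REPEAT_RE = re.compile(r"\((\d+)(?:,(\d+))?\)$")


def _parse_element(token: str, index: int) -> PatternElement:
    min_rep = max_rep = 1
    m = _REPEAT_RE.search(token)
    if m:
        min_rep = int(m.group(1))
        max_rep = int(m.group(2)) if m.group(2) else min_rep
        if min_rep < 1:
            raise PatternSyntaxError("repeat count must be positive", index)
        if max_rep < min_rep:
            raise PatternSyntaxError("repeat range is inverted", index)
        token = token[: m.start()]
    elif "(" in token or ")" in token:
        raise PatternSyntaxError(f"malformed repeat in {token!r}", index)

    if not token:
        raise PatternSyntaxError("empty element", index)

    if token in ("x", "X"):
        return PatternElement(ElementKind.ANY, frozenset(), min_rep, max_rep)

    for opener, closer, kind in (
        ("[", "]", ElementKind.CLASS),
        ("{", "}", ElementKind.NEGATED_CLASS),
    ):
        if token.startswith(opener):
            if not token.endswith(closer) or len(token) < 3:
                raise PatternSyntaxError(
                    f"unclosed or empty bracket in {token!r}", index
                )
            inner = token[1:-1].upper()
            bad = set(inner) - VALID_SEQ_LETTERS
            if bad:
                raise PatternSyntaxError(
                    f"invalid residue letters {sorted(bad)} in {token!r}", index
                )
            return PatternElement(kind, frozenset(inner), min_rep, max_rep)
        if token.endswith(closer):
            raise PatternSyntaxError(f"unmatched {closer!r} in {token!r}", index)

    if len(token) == 1 and token.upper() in VALID_SEQ_LETTERS:
        return PatternElement(
            ElementKind.LITERAL, frozenset(token.upper()), min_rep, max_rep
        )
    raise PatternSyntaxError(f"unrecognized element {token!r}", index)


def parse_pattern(text: str) -> PrositePattern:
    """Parse a PROSITE-style pattern string.

    Raises :class:`PatternSyntaxError` naming the 1-based offending element
    on any malformed input; nothing is silently skipped.
    """
    if not isinstance(text, str) or not text.strip():
        raise PatternSyntaxError("pattern is empty", 1)
    body = text.strip()
    if body.endswith("."):  # PROSITE database entries end with a period
        body = body[:-1]
    anchored_start = body.startswith("<")
    if anchored_start:
        body = body[1:]
    anchored_end = body.endswith(">")
    if anchored_end:
        body = body[:-1]
    if not body:
        raise PatternSyntaxError("pattern has anchors but no elements", 1)

    elements = tuple(
        _parse_element(tok, i + 1) for i, tok in enumerate(body.split("-"))
    )
    return PrositePattern(text.strip(), elements, anchored_start, anchored_end)


@dataclass(frozen=True)
class MatchSpan:
    """A single occurrence: 1-based inclusive coordinates."""

    start: int
    end: int
    matched_text: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError("invalid span coordinates")
        if self.end - self.start + 1 != len(self.matched_text):
            raise ValueError("span length disagrees with matched text")


def normalize_sequence(sequence: str) -> str:
    """Upper-case a protein sequence and validate its alphabet.

    A single trailing ``*`` (translation stop) is tolerated and removed.
    """
    seq = sequence.strip().upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    for i, ch in enumerate(seq):
        if ch not in VALID_SEQ_LETTERS:
            raise SequenceError(f"invalid residue {ch!r}", i + 1)
    return seq


def _extensions(
    pattern: PrositePattern, seq: str, elem_idx: int, pos: int
) -> Iterator[int]:
    """Yield end offsets (exclusive) of all ways to match elements[elem_idx:]
    starting at ``pos``.  Backtracking search; repeat counts are tiny in
    practice so this is not a hot spot."""
    if elem_idx == len(pattern.elements):
        yield pos
        return
    elem = pattern.elements[elem_idx]
    # consume the mandatory repeats, then branch on the optional ones
    p = pos
    for _ in range(elem.min_repeat):
        if p >= len(seq) or not elem.matches(seq[p]):
            return
        p += 1
    for extra in range(elem.max_repeat - elem.min_repeat + 1):
        if extra > 0:
            q = p + extra - 1
            if q >= len(seq) or not elem.matches(seq[q]):
                return
        yield from _extensions(pattern, seq, elem_idx + 1, p + extra)


def find_matches(pattern: PrositePattern, sequence: str) -> list[MatchSpan]:
    """Report every occurrence of ``pattern`` in ``sequence``.

    Overlapping occurrences are all reported.  When repeat ranges allow
    several spans from one start, each distinct span is reported once.
    Spans are sorted by start, then end.
    """
    seq = normalize_sequence(sequence)
    spans: set[tuple[int, int]] = set()
    starts = range(1) if pattern.anchored_start else range(len(seq))
    for start in starts:
        for end in _extensions(pattern, seq, 0, start):
            if pattern.anchored_end and end != len(seq):
                continue
            if end > start:  # zero-length matches cannot arise (min_repeat>=1)
                spans.add((start, end))
    return [
        MatchSpan(s + 1, e, seq[s:e]) for s, e in sorted(spans)
    ]
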