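"""Pattern grammar, matching semantics and oracle equivalence."""

import pytest
from hypothesis import given, strategies as st

from gt43scan.prosite import (
    ElementKind,
    PatternSyntaxError,
    SequenceError,
    find_matches,
    parse_pattern,
)

from oracles import regex_find_matches


class TestParse:
    def test_literal_and_class_elements(self):
        p = parse_pattern("T-P-[TI]-[YI]")
        assert [e.kind for e in p.elements] == [
            ElementKind.LITERAL, ElementKind.LITERAL,
            ElementKind.CLASS, ElementKind.CLASS,
        ]
        assert p.elements[2].residues == frozenset("TI")
        assert p.min_span == p.max_span == 4

    def test_class_sizes(self):
        p = parse_pattern("W-[HRNW]-[LT]-[RQKH]")
        assert [len(e.residues) for e in p.elements] == [1, 4, 2, 4]

    def test_wildcard_negation_repeats_anchors(self):
        p = parse_pattern("<A-x(2,4)-{PG}-C(3)>")
        assert p.anchored_start and p.anchored_end
        kinds = [e.kind for e in p.elements]
        assert kinds == [
            ElementKind.LITERAL, ElementKind.ANY,
            ElementKind.NEGATED_CLASS, ElementKind.LITERAL,
        ]
        assert (p.elements[1].min_repeat, p.elements[1].max_repeat) == (2, 4)
        assert p.min_span == 1 + 2 + 1 + 3
        assert p.max_span == 1 + 4 + 1 + 3

    def test_round_trip_rendering(self):
        for text in ["T-P-[TI]-[YI]", "x(2)-{PG}-W", "<A-[BX]-C>"]:
            p = parse_pattern(text)
            assert parse_pattern(p.render()).render() == p.render()

    @pytest.mark.parametrize(
        "bad, index",
        [
            ("T--P", 2),
            ("", 1),
            ("[", 1),
            ("A-[]-B", 2),
            ("A-[QR", 2),
            ("A-B(0)", 2),
            ("A-B(3,2)", 2),
            ("A-B)", 2),
            ("A-zz", 2),
        ],
    )
    def test_syntax_errors_name_the_element(self, bad, index):
        with pytest.raises(PatternSyntaxError) as exc:
            parse_pattern(bad)
        assert exc.value.element_index == index


class TestFindMatches:
    def test_single_hit(self):
        spans = find_matches(parse_pattern("D-D-[DS]-N"), "ADDSNA")
        assert [(s.start, s.end, s.matched_text) for s in spans] == [
            (2, 5, "DDSN")
        ]

    def test_tandem_hits(self):
        spans = find_matches(parse_pattern("T-P-[TI]-[YI]"), "TPTYTPII")
        assert [(s.start, s.end) for s in spans] == [(1, 4), (5, 8)]

    def test_no_hit(self):
        assert find_matches(parse_pattern("[QMN]-R-[NL]"), "AAAAAA") == []

    def test_overlapping_hits_all_reported(self):
        spans = find_matches(parse_pattern("A-A"), "AAAA")
        assert [(s.start, s.end) for s in spans] == [(1, 2), (2, 3), (3, 4)]

    def test_case_insensitive(self):
        assert find_matches(parse_pattern("D-D-[DS]-N"), "addsna")

    def test_x_matches_wildcard_only(self):
        assert find_matches(parse_pattern("x-x"), "AX")
        assert find_matches(parse_pattern("A-[TX]"), "AX")
        assert not find_matches(parse_pattern("A-[TS]"), "AX")
        assert not find_matches(parse_pattern("A-{P}"), "AX")

    def test_invalid_residue_reports_position(self):
        with pytest.raises(SequenceError) as exc:
            find_matches(parse_pattern("A-A"), "AA1A")
        assert exc.value.position == 3

    def test_variable_repeat_yields_multiple_spans_per_start(self):
        spans = find_matches(parse_pattern("A-x(1,3)-C"), "AGGGC")
        assert [(s.start, s.end) for s in spans] == [(1, 5)]
        spans = find_matches(parse_pattern("A-G(1,3)"), "AGGG")
        assert [(s.start, s.end) for s in spans] == [(1, 2), (1, 3), (1, 4)]


# --- randomized oracle equivalence -------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"

_literal = st.sampled_from(_AA).map(lambda a: a)
_class = st.sets(st.sampled_from(_AA + "X"), min_size=1, max_size=5).map(
    lambda s: "[" + "".join(sorted(s)) + "]"
)
_negated = st.sets(st.sampled_from(_AA), min_size=1, max_size=3).map(
    lambda s: "{" + "".join(sorted(s)) + "}"
)
_repeat = st.one_of(
    st.just(""),
    st.integers(1, 3).map(lambda n: f"({n})"),
    st.tuples(st.integers(1, 2), st.integers(0, 2)).map(
        lambda t: f"({t[0]},{t[0] + t[1]})"
    ),
)
_element = st.tuples(st.one_of(_literal, _class, _negated, st.just("x")),
                     _repeat).map("".join)
pattern_texts = st.lists(_element, min_size=1, max_size=6).map("-".join)
sequences = st.text(alphabet=_AA + "X", min_size=0, max_size=200)


@given(pattern_texts, sequences)
def test_matcher_equals_regex_oracle(text, seq):
    """Backtracking matcher agrees with a regex-window oracle on random
    patterns and sequences."""
    pattern = parse_pattern(text)
    got = [(s.start, s.end) for s in find_matches(pattern, seq)]
    assert got == regex_find_matches(pattern, seq)


@given(pattern_texts, sequences, st.integers(1, 30))
def test_shift_equivariance(text, seq, k):
    """Prepending residues that cannot start a match shifts spans by k."""
    pattern = parse_pattern(text)
    if pattern.anchored_start or pattern.anchored_end:
        return
    base = [(s.start, s.end) for s in find_matches(pattern, seq)]
    first = pattern.elements[0]
    blocked = [c for c in _AA if not first.matches(c)]
    if not blocked:
        return
    prefix = blocked[0] * k
    shifted = [(s.start, s.end) for s in find_matches(pattern, prefix + seq)]
    # drop any new matches that straddle the boundary using the prefix tail
    expected = [(a + k, b + k) for a, b in base]
    assert [s for s in shifted if s[0] > k] == expected


@given(pattern_texts, sequences)
def test_matched_text_rematches(text, seq):
    pattern = parse_pattern(text)
    if pattern.anchored_start or pattern.anchored_end:
        return
    for span in find_matches(pattern, seq):
        sub = find_matches(pattern, span.matched_text)
        assert any(
            s.start == 1 and s.end == len(span.matched_text) for s in sub
        )
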