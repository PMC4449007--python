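"""FASTA round trips, HMMER/BLAST table parsing, family annotation."""

import itertools

import pytest

from gt43scan.evidence_io import (
    BlastHit,
    ProteinRecord,
    annotate,
    best_hit,
    best_hits_per_query,
    load_family_map,
    parse_blast_tab,
    parse_domtbl,
    read_fasta,
    write_fasta,
)


# A miniature hmmsearch --domtblout excerpt (synthetic layout, real column
# structure): target, -, tlen, query model, -, qlen, full E-value, score,
# bias, #, of, c-Evalue, i-Evalue, dom score, bias, coords..., acc, desc.
DOMTBL = """\
# mock domtbl
#
XP_004345176.1 - 390 GT43 - 250 1.5e-59 200.1 0.1 1 1 1.5e-59 1.5e-59 200.0 0.1 1 250 10 260 5 270 0.95 -
Q1 - 400 GT43 - 250 1e-3 20.0 0.1 1 2 2e-3 1e-3 18.0 0.1 1 100 5 110 1 120 0.90 -
Q1 - 400 GT43 - 250 1e-3 20.0 0.1 2 2 1e-20 1e-20 60.0 0.1 120 240 130 250 125 255 0.92 -
Q2 - 300 OTHER - 250 1e-40 150.0 0.1 1 1 1e-40 1e-40 150.0 0.1 1 250 1 260 1 270 0.99 -
"""


class TestFasta:
    def test_read_single_record(self, tmp_path):
        p = tmp_path / "a.faa"
        p.write_text(">a desc here\nMKV\n")
        (rec,) = read_fasta(p)
        assert (rec.seq_id, rec.description, rec.sequence, rec.length) == (
            "a", "desc here", "MKV", 3
        )

    def test_round_trip_many_records(self, tmp_path):
        import random

        rng = random.Random(0)
        records = [
            ProteinRecord(
                f"id{i}", f"desc {i}",
                "".join(rng.choices("ACDEFGHIKLMNPQRSTVWY", k=rng.randint(1, 150))),
            )
            for i in range(50)
        ]
        p = tmp_path / "rt.faa"
        write_fasta(records, p)
        assert read_fasta(p) == records

    def test_terminal_stop_stripped(self, tmp_path):
        p = tmp_path / "s.faa"
        p.write_text(">a\nMKV*\n")
        assert read_fasta(p)[0].sequence == "MKV"

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.faa"
        p.write_text(">a\nMK\n>a\nVL\n")
        with pytest.raises(ValueError, match="'a'"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.faa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p)


class TestDomtbl:
    def test_parses_named_model_only(self, tmp_path):
        p = tmp_path / "t.domtbl"
        p.write_text(DOMTBL)
        hits = parse_domtbl(p, "GT43")
        assert [h.query_id for h in hits] == ["XP_004345176.1", "Q1"]
        assert hits[0].best_domain_ievalue == 1.5e-59

    def test_minimum_ievalue_kept_across_rows(self, tmp_path):
        p = tmp_path / "t.domtbl"
        p.write_text(DOMTBL)
        (q1,) = [h for h in parse_domtbl(p, "GT43") if h.query_id == "Q1"]
        assert q1.best_domain_ievalue == 1e-20
        assert q1.full_seq_evalue == 1e-3

    def test_comment_only_file(self, tmp_path):
        p = tmp_path / "c.domtbl"
        p.write_text("# nothing\n#\n")
        assert parse_domtbl(p, "GT43") == []

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.domtbl"
        p.write_text("# ok\nshort row\n")
        with pytest.raises(ValueError, match=":2"):
            parse_domtbl(p, "GT43")


class TestBestHit:
    def test_min_evalue_wins(self):
        h1 = BlastHit("q", "s1", 1e-5, 50, 0)
        h2 = BlastHit("q", "s2", 1e-20, 90, 1)
        assert best_hit([h1, h2]).subject_id == "s2"

    def test_evalue_tie_broken_by_bitscore(self):
        h1 = BlastHit("q", "s1", 1e-20, 90, 0)
        h2 = BlastHit("q", "s2", 1e-20, 95, 1)
        assert best_hit([h1, h2]).subject_id == "s2"

    def test_full_tie_broken_by_file_order(self):
        h1 = BlastHit("q", "s1", 1e-20, 90, 0)
        h2 = BlastHit("q", "s2", 1e-20, 90, 1)
        assert best_hit([h2, h1]).subject_id == "s1"

    def test_no_hits_is_absent_not_error(self):
        assert best_hit([]) is None

    def test_permutation_invariant(self):
        hits = [
            BlastHit("q", f"s{i}", e, b, i)
            for i, (e, b) in enumerate([(1e-5, 50), (1e-20, 90), (1e-20, 85)])
        ]
        winners = {
            best_hit(list(perm)).subject_id
            for perm in itertools.permutations(hits)
        }
        assert winners == {"s1"}

    def test_blast_tab_best_hit_fixture(self, tmp_path):
        rows = [
            ["XP_001744836.1", "CAI60000.1", "30.0", "100", "70", "2",
             "1", "100", "1", "100", "1e-10", "60.0"],
            ["XP_001744836.1", "AFE77696.1", "55.0", "280", "120", "3",
             "1", "280", "1", "280", "6.8e-42", "160.0"],
        ]
        p = tmp_path / "b.tsv"
        p.write_text("".join("\t".join(r) + "\n" for r in rows))
        best = best_hits_per_query(parse_blast_tab(p))["XP_001744836.1"]
        assert best.subject_id == "AFE77696.1"
        assert best.evalue == 6.8e-42


class TestFamilyMap:
    def test_lookup(self, tmp_path):
        p = tmp_path / "fam.tsv"
        p.write_text("CAI62038.1\tGT43\nOTHER.1\tGT2\n")
        fam = load_family_map(p)
        hit = BlastHit("q", "CAI62038.1", 1e-25, 100, 0)
        rec = annotate("q", None, hit, fam)
        assert rec.best_hit_family == "GT43"

    def test_missing_accession_becomes_unknown(self, tmp_path, caplog):
        hit = BlastHit("q", "NOPE.1", 1e-25, 100, 0)
        rec = annotate("q", None, hit, {})
        assert rec.best_hit_family == "UNKNOWN"

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("GOOD.1\tGT43\nonly_one_column\n")
        with pytest.raises(ValueError, match=":2"):
            load_family_map(p)
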