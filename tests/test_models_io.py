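"""Clone identity, productivity rules, and TSV round trips."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonotrack import filter_functional, make_clone_key, read_repertoire, write_repertoire
from clonotrack.errors import (
    InvalidSequenceError,
    MissingColumnError,
    NegativeCountError,
    SubsetFractionError,
)
from clonotrack.io import MITCR_COLUMN_MAP
from clonotrack.models import (
    Clonotype,
    SubsetFractionTable,
    is_functional,
    translate_junction,
)
from conftest import make_sample, nth_cdr3


class TestCloneKey:
    def test_allele_stripped(self):
        a = Clonotype(v_call="TRBV12-3*01", cdr3_nt=nth_cdr3(0), count=1)
        b = Clonotype(v_call="TRBV12-3*02", cdr3_nt=nth_cdr3(0), count=5)
        assert make_clone_key(a) == make_clone_key(b)

    def test_single_nt_difference_separates_clones(self):
        s = nth_cdr3(0)
        s2 = s[:4] + ("A" if s[4] != "A" else "G") + s[5:]
        a = Clonotype(v_call="TRBV9*01", cdr3_nt=s, count=1)
        b = Clonotype(v_call="TRBV9*01", cdr3_nt=s2, count=1)
        assert make_clone_key(a) != make_clone_key(b)

    def test_deterministic(self):
        c = Clonotype(v_call="TRBV9*01", cdr3_nt=nth_cdr3(3), count=1)
        assert make_clone_key(c) == make_clone_key(c)


class TestProductivity:
    @pytest.mark.parametrize(
        "nt,expected",
        [
            (nth_cdr3(0), True),  # C...F in frame, stop-free
            ("TGT" + "TAA" + "TTT", False),  # internal stop
            (nth_cdr3(0)[:-1], False),  # out of frame (length 3k+2)
            ("TGTGCAGCATTG", False),  # ends L, anchor fails
            ("GCAGCAGCATTT", False),  # does not start with C
        ],
    )
    def test_functionality_rule(self, nt, expected):
        assert is_functional(nt) is expected

    def test_anchor_relaxation(self):
        assert is_functional("GCAGCAGCATTG", require_anchors=False)

    def test_translation_marks_stops(self):
        assert translate_junction("TGTTAGTTT") == "C*F"

    def test_filter_keeps_productive_only(self):
        s = make_sample({"a": 5, "b": 3})
        s.clonotypes.append(
            Clonotype(v_call="TRBV9*01", cdr3_nt="TGTTAATTT", count=7, productive=False)
        )
        out = filter_functional(s)
        assert len(out.clonotypes) == 2
        assert out.total_functional == 8

    def test_filter_idempotent_and_nonincreasing(self):
        s = make_sample({"a": 5, "b": 3, "c": 2})
        once = filter_functional(s)
        twice = filter_functional(once)
        assert once.total_functional == twice.total_functional == 10
        assert [make_clone_key(c) for c in once.clonotypes] == [
            make_clone_key(c) for c in twice.clonotypes
        ]


class TestReadWrite:
    def test_round_trip_bit_stable(self, tmp_path):
        s = make_sample({"a": 500, "b": 30, "c": 1})
        p = tmp_path / "rep.tsv"
        write_repertoire(s, p)
        back = read_repertoire(
            p, sample_id="s1", subject_id="RA1", tissue="PB",
            subset="memory", timepoint="t0", platform="bulk-NGS",
        )
        assert back.key_counts() == s.key_counts()
        assert {make_clone_key(c): c.productive for c in back.clonotypes} == {
            make_clone_key(c): c.productive for c in s.clonotypes
        }
        # second round trip is byte-identical
        p2 = tmp_path / "rep2.tsv"
        write_repertoire(back, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_merge_rows_with_same_key(self, tmp_path):
        p = tmp_path / "rep.tsv"
        cdr3 = nth_cdr3(0)
        pd.DataFrame(
            {
                "v_call": ["TRBV12-3*01", "TRBV12-3*02"],
                "junction": [cdr3, cdr3],
                "duplicate_count": [3, 5],
            }
        ).to_csv(p, sep="\t", index=False)
        s = read_repertoire(p, "s1", "RA1", "PB", "memory", "t0", "bulk-NGS")
        assert len(s.clonotypes) == 1
        assert s.clonotypes[0].count == 8

    def test_internal_stop_read_as_nonproductive(self, tmp_path):
        p = tmp_path / "rep.tsv"
        pd.DataFrame(
            {"v_call": ["TRBV9*01"], "junction": ["TGTTAGTTT"], "duplicate_count": [4]}
        ).to_csv(p, sep="\t", index=False)
        s = read_repertoire(p, "s1", "RA1", "PB", "memory", "t0", "bulk-NGS")
        assert s.clonotypes[0].productive is False

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "rep.tsv"
        pd.DataFrame({"v_call": ["TRBV9*01"], "junction": [nth_cdr3(0)]}).to_csv(
            p, sep="\t", index=False
        )
        with pytest.raises(MissingColumnError):
            read_repertoire(p, "s1", "RA1", "PB", "memory", "t0", "bulk-NGS")

    def test_non_dna_junction_raises(self, tmp_path):
        p = tmp_path / "rep.tsv"
        pd.DataFrame(
            {"v_call": ["TRBV9*01"], "junction": ["TGTNNNTTT"], "duplicate_count": [1]}
        ).to_csv(p, sep="\t", index=False)
        with pytest.raises(InvalidSequenceError):
            read_repertoire(p, "s1", "RA1", "PB", "memory", "t0", "bulk-NGS")

    def test_negative_count_raises(self, tmp_path):
        p = tmp_path / "rep.tsv"
        pd.DataFrame(
            {"v_call": ["TRBV9*01"], "junction": [nth_cdr3(0)], "duplicate_count": [-2]}
        ).to_csv(p, sep="\t", index=False)
        with pytest.raises(NegativeCountError):
            read_repertoire(p, "s1", "RA1", "PB", "memory", "t0", "bulk-NGS")

    def test_mitcr_dialect_via_column_map(self, tmp_path):
        p = tmp_path / "mitcr.tsv"
        pd.DataFrame(
            {
                "V segments": ["TRBV9"],
                "CDR3 nucleotide sequence": [nth_cdr3(1)],
                "Read count": [12],
            }
        ).to_csv(p, sep="\t", index=False)
        s = read_repertoire(
            p, "s1", "RA1", "PB", "memory", "t0", "bulk-NGS",
            column_map=MITCR_COLUMN_MAP,
        )
        assert s.clonotypes[0].count == 12


class TestSubsetFractions:
    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(SubsetFractionError):
            SubsetFractionTable(rows=[("RA1", "t0", "memory", 1.2)])

    def test_helper_leaves_cannot_exceed_memory_gate(self):
        rows = [
            ("RA1", "t0", "memory", 0.4),
            ("RA1", "t0", "Th1", 0.2),
            ("RA1", "t0", "Th17", 0.2),
            ("RA1", "t0", "Tfh", 0.1),
        ]
        with pytest.raises(SubsetFractionError):
            SubsetFractionTable(rows=rows)

    def test_leaves_need_not_partition_memory(self):
        table = SubsetFractionTable(
            rows=[("RA1", "t0", "memory", 0.4), ("RA1", "t0", "Th1", 0.1)]
        )
        assert table.fraction("RA1", "t0", "Th1") == 0.1


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=10_000), min_size=1, max_size=30)
)
def test_round_trip_preserves_any_count_table(tmp_path_factory, counts):
    """Write→read preserves keys, counts and productivity for arbitrary tables."""
    s = make_sample(counts)
    p = tmp_path_factory.mktemp("rt") / "rep.tsv"
    write_repertoire(s, p)
    back = read_repertoire(p, "s1", "RA1", "PB", "memory", "t0", "bulk-NGS")
    assert back.key_counts() == s.key_counts()
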