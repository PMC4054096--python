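"""SAM ingestion: coordinates, strand, duplicate collapsing, mutations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clipdiff.ingest import (
    AlignedTag,
    IngestConfig,
    Mutation,
    collapse_duplicates,
    read_alignments,
    write_mutation_table,
)
from tests.conftest import sam_line


def read_all(path, condition=1, **kw):
    return list(read_alignments(path, condition, IngestConfig(**kw)))


class TestReadAlignments:
    def test_coordinates_and_strand(self, write_sam):
        # 1-based SAM POS 101 with 20M -> 0-based half-open [100, 120)
        path = write_sam([
            sam_line("fwd", 0, "chr1", 101, "20M", "A" * 20),
            sam_line("rev", 16, "chr1", 101, "20M", "A" * 20),
            sam_line("unmapped", 4, "*", 0, "*", "A" * 20),
        ])
        tags = read_all(path)
        assert len(tags) == 2
        assert (tags[0].start, tags[0].end, tags[0].strand) == (100, 120, "+")
        assert (tags[1].start, tags[1].end, tags[1].strand) == (100, 120, "-")

    def test_soft_clips_excluded_from_span(self, write_sam):
        path = write_sam([sam_line("sc", 0, "chr1", 101, "5S10M5S", "A" * 20)])
        (tag,) = read_all(path)
        assert (tag.start, tag.end) == (100, 110)

    def test_mapping_quality_filter(self, write_sam):
        path = write_sam([
            sam_line("low", 0, "chr1", 101, "20M", "A" * 20, mapq=5),
            sam_line("high", 0, "chr1", 201, "20M", "A" * 20, mapq=30),
        ])
        assert len(read_all(path)) == 2
        assert [t.start for t in read_all(path, min_mapping_quality=10)] == [200]

    def test_secondary_and_supplementary_skipped(self, write_sam):
        path = write_sam([
            sam_line("sec", 256, "chr1", 101, "20M", "A" * 20),
            sam_line("sup", 2048, "chr1", 101, "20M", "A" * 20),
        ])
        assert read_all(path) == []

    def test_condition_label_is_the_only_difference(self, write_sam):
        path = write_sam([
            sam_line("a", 0, "chr1", 101, "10M1D10M", "A" * 20, md="10^G10"),
            sam_line("b", 16, "chr2", 51, "30M", "C" * 30),
        ])
        t1 = read_all(path, condition=1, mutation_type="deletion")
        t2 = read_all(path, condition=2, mutation_type="deletion")
        for a, b in zip(t1, t2):
            assert (a.key, a.mutations) == (b.key, b.mutations)
            assert (a.condition, b.condition) == (1, 2)

    def test_paired_end_fragment_spans_outer_coordinates(self, tmp_path):
        # proper pair: read1 [100,120), mate [160,180) -> one tag [100,180)
        header = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n"
        rec1 = ("frag\t99\tchr1\t101\t255\t20M\t=\t161\t80\t" + "A" * 20 + "\t" + "I" * 20 + "\n")
        rec2 = ("frag\t147\tchr1\t161\t255\t20M\t=\t101\t-80\t" + "A" * 20 + "\t" + "I" * 20 + "\n")
        path = tmp_path / "pe.sam"
        path.write_text(header + rec1 + rec2)
        tags = read_all(str(path), paired_end=True)
        assert len(tags) == 1
        assert (tags[0].start, tags[0].end, tags[0].strand) == (100, 180, "+")

    def test_missing_file_is_fatal(self):
        with pytest.raises(OSError):
            read_all("/nonexistent/file.sam")


class TestExtractMutations:
    def test_deletion_position_from_cigar(self, write_sam):
        # POS 101, 10M1D10M -> deletion at 0-based reference position 110
        path = write_sam([sam_line("d", 0, "chr1", 101, "10M1D10M", "A" * 20,
                                   md="10^G10")])
        (tag,) = read_all(path, mutation_type="deletion")
        assert len(tag.mutations) == 1
        mut = tag.mutations[0]
        assert (mut.kind, mut.pos, mut.ref_base) == ("deletion", 110, "G")
        assert mut.alt_base is None

    def test_deletion_without_md_has_unknown_ref(self, write_sam):
        path = write_sam([sam_line("d", 0, "chr1", 101, "10M1D10M", "A" * 20)])
        (tag,) = read_all(path, mutation_type="deletion")
        assert tag.mutations[0].ref_base == "N"
        assert tag.mutations[0].pos == 110

    def test_perfect_match_yields_no_mutations(self, write_sam):
        path = write_sam([sam_line("m", 0, "chr1", 101, "20M", "A" * 20, md="20")])
        (tag,) = read_all(path, mutation_type="T2C")
        assert tag.mutations == []

    def test_t2c_substitution_on_plus_strand(self, write_sam):
        # MD 9T10 with read base C at offset 9: T->C at reference offset 9
        seq = "A" * 9 + "C" + "A" * 10
        path = write_sam([sam_line("s", 0, "chr1", 101, "20M", seq, md="9T10")])
        (tag,) = read_all(path, mutation_type="T2C")
        (mut,) = tag.mutations
        assert (mut.kind, mut.pos, mut.ref_base, mut.alt_base, mut.strand) == (
            "substitution", 109, "T", "C", "+")

    def test_t2c_complements_on_minus_strand(self, write_sam):
        # a minus-strand tag shows T->C as A->G in reference orientation
        seq_ag = "C" * 9 + "G" + "C" * 10
        seq_tc = "A" * 9 + "C" + "A" * 10
        path = write_sam([
            sam_line("keep", 16, "chr1", 101, "20M", seq_ag, md="9A10"),
            sam_line("drop", 16, "chr1", 201, "20M", seq_tc, md="9T10"),
        ])
        tags = read_all(path, mutation_type="T2C")
        assert [len(t.mutations) for t in tags] == [1, 0]
        assert (tags[0].mutations[0].ref_base, tags[0].mutations[0].alt_base) == ("A", "G")

    def test_g2a_profile(self, write_sam):
        seq = "T" * 4 + "A" + "T" * 15
        path = write_sam([sam_line("g", 0, "chr1", 101, "20M", seq, md="4G15")])
        (tag,) = read_all(path, mutation_type="G2A")
        assert (tag.mutations[0].pos, tag.mutations[0].ref_base) == (104, "G")

    def test_substitution_profiling_without_md_is_fatal(self, write_sam):
        path = write_sam([sam_line("x", 0, "chr1", 101, "20M", "A" * 20)])
        with pytest.raises(ValueError, match="MD"):
            read_all(path, mutation_type="T2C")

    def test_mutation_table_output(self, write_sam, tmp_path):
        path = write_sam([sam_line("d", 0, "chr1", 101, "10M1D10M", "A" * 20,
                                   md="10^G10")])
        tags = read_all(path, mutation_type="deletion")
        out = tmp_path / "muts.tsv"
        assert write_mutation_table(tags, str(out)) == 1
        lines = out.read_text().splitlines()
        assert lines[1].split("\t") == ["chr1", "110", "+", "deletion", "G", ".", "1"]


def make_tag(chrom, start, end, strand, condition=1, muts=()):
    return AlignedTag(chrom, start, end, strand, condition, list(muts))


class TestCollapseDuplicates:
    def test_strand_distinguishes(self):
        tags = [make_tag("chr1", 100, 120, "+")] * 3 + [make_tag("chr1", 100, 120, "-")]
        assert len(collapse_duplicates(tags)) == 2

    def test_five_identical_collapse_to_one(self):
        assert len(collapse_duplicates([make_tag("chr1", 100, 120, "+")] * 5)) == 1

    def test_different_end_not_collapsed(self):
        tags = [make_tag("chr1", 100, 120, "+"), make_tag("chr1", 100, 121, "+")]
        assert len(collapse_duplicates(tags)) == 2

    def test_mutations_merged_as_distinct_union(self):
        m1 = Mutation("deletion", "chr1", 110, "N", None, "+")
        m2 = Mutation("deletion", "chr1", 111, "N", None, "+")
        tags = [make_tag("chr1", 100, 120, "+", muts=[m1]),
                make_tag("chr1", 100, 120, "+", muts=[m1, m2])]
        (kept,) = collapse_duplicates(tags)
        assert sorted(m.pos for m in kept.mutations) == [110, 111]

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.sampled_from(["chr1", "chr2"]),
                              st.integers(0, 50), st.integers(1, 20),
                              st.sampled_from("+-")), max_size=40))
    def test_matches_set_oracle_and_idempotent(self, raw):
        tags = [make_tag(c, s, s + l, strand) for c, s, l, strand in raw]
        collapsed = collapse_duplicates(tags)
        assert len(collapsed) == len({t.key for t in tags})
        again = collapse_duplicates(collapsed)
        assert [t.key for t in again] == [t.key for t in collapsed]


def test_aligned_tag_invariants():
    with pytest.raises(ValueError):
        AlignedTag("chr1", 10, 10, "+", 1)
    with pytest.raises(ValueError):
        AlignedTag("chr1", 0, 10, "+", 3)
    with pytest.raises(ValueError):
        Mutation("substitution", "chr1", 5, "T", "T", "+")
    with pytest.raises(ValueError):
        Mutation("deletion", "chr1", 5, "T", "C", "+")
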