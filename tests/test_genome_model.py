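"""Coordinate arithmetic, annotation and coverage I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regulome.genome_model import (
    CoverageTrack,
    GeneRecord,
    GenomeAnnotation,
    ReadAlignment,
    SampleInfo,
    SampleSheet,
    StrandedInterval,
    Terminator,
    antisense_overlap,
    coverage_from_reads,
    interval_length,
    read_annotation,
    read_coverage,
    read_sample_sheet,
    read_terminators,
    write_annotation,
    write_coverage,
    write_sample_sheet,
    write_terminators,
)


def iv(start, end, strand="+", chrom="chr"):
    return StrandedInterval(chrom, start, end, strand)


class TestIntervalLength:
    @pytest.mark.parametrize("printed,expected", [
        ((210580, 210926), 347),   # published 5'UTR span
        ((5, 5), 1),               # single base
        ((3332662, 3328698), 3965),  # minus-strand printed pair
        ((2118173, 2117083), 1091),
        ((54282, 49490), 4793),
    ])
    def test_published_spans(self, printed, expected):
        interval = StrandedInterval.from_printed("chr", *printed)
        assert interval_length(interval) == expected

    def test_matches_brute_force_counting(self, rng):
        for _ in range(1000):
            a, b = sorted(rng.integers(1, 10_000, 2))
            interval = iv(int(a), int(b))
            assert interval_length(interval) == len(range(a, b + 1))

    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            iv(10, 5)
        with pytest.raises(ValueError):
            iv(0, 5)
        with pytest.raises(ValueError):
            StrandedInterval("chr", 1, 5, "*")

    def test_printed_notation_round_trip(self):
        minus = iv(3328698, 3332662, "-")
        assert minus.to_printed() == (3332662, 3328698)
        assert StrandedInterval.from_printed("chr", *minus.to_printed()) == minus
        plus = iv(100, 300, "+")
        assert plus.to_printed() == (100, 300)


class TestAntisenseOverlap:
    @pytest.mark.parametrize("a,b,expected", [
        (iv(100, 300, "+"), iv(100, 300, "-"), 201),
        (iv(100, 300, "+"), iv(400, 500, "-"), 0),
        (iv(100, 300, "+"), iv(250, 500, "-"), 51),
        (iv(100, 300, "+"), iv(250, 500, "+"), 0),  # same strand
    ])
    def test_examples(self, a, b, expected):
        assert antisense_overlap(a, b) == expected
        assert antisense_overlap(b, a) == expected

    @given(st.integers(1, 500), st.integers(0, 200),
           st.integers(1, 500), st.integers(0, 200))
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_equals_set_intersection(self, s1, l1, s2, l2):
        a = iv(s1, s1 + l1, "+")
        b = iv(s2, s2 + l2, "-")
        expected = len(set(range(a.start, a.end + 1))
                       & set(range(b.start, b.end + 1)))
        assert antisense_overlap(a, b) == expected
        assert antisense_overlap(b, a) == expected

    def test_different_chromosomes(self):
        assert antisense_overlap(iv(1, 10, "+"),
                                 iv(1, 10, "-", chrom="other")) == 0


class TestCoverage:
    def test_stacked_reads(self):
        reads = [ReadAlignment(iv(1, 50, "+"))] * 2
        track = coverage_from_reads(reads, 100)
        assert (track.fwd[:50] == 2).all() and track.fwd[50:].sum() == 0
        assert track.rev.sum() == 0

    def test_no_reads_is_zero(self):
        assert coverage_from_reads([], 100).total_activity() == 0

    def test_overlapping_reads_per_base(self):
        reads = [ReadAlignment(iv(1, 50, "+")), ReadAlignment(iv(26, 75, "+"))]
        track = coverage_from_reads(reads, 100)
        assert (track.fwd[25:50] == 2).all()
        assert (track.fwd[:25] == 1).all() and (track.fwd[50:75] == 1).all()

    def test_circular_wrap(self):
        track = coverage_from_reads([ReadAlignment(iv(95, 104, "+"))], 100,
                                    circular=True)
        assert (track.fwd[94:] == 1).all() and (track.fwd[:4] == 1).all()
        with pytest.raises(ValueError):
            coverage_from_reads([ReadAlignment(iv(95, 104, "+"))], 100)

    def test_total_activity_is_reads_times_length(self, rng):
        reads = [ReadAlignment(iv(int(s), int(s) + 49, "+"))
                 for s in rng.integers(1, 900, 40)]
        track = coverage_from_reads(reads, 1000)
        assert track.total_activity() == 40 * 50


class TestBedgraphIO:
    def test_zero_track_empty_body(self, tmp_path):
        track = CoverageTrack(100)
        write_coverage(track, tmp_path / "p.bg", tmp_path / "m.bg")
        assert (tmp_path / "p.bg").read_text() == ""

    def test_coordinate_convention(self, tmp_path):
        track = CoverageTrack(20)
        track.fwd[9:12] = 3  # 1-based bases 10..12
        write_coverage(track, tmp_path / "p.bg", tmp_path / "m.bg")
        assert (tmp_path / "p.bg").read_text() == "chr\t9\t12\t3\n"

    def test_random_round_trip(self, tmp_path, rng):
        track = CoverageTrack(500,
                              rng.integers(0, 5, 500),
                              rng.integers(0, 5, 500))
        write_coverage(track, tmp_path / "p.bg", tmp_path / "m.bg")
        assert read_coverage(tmp_path / "p.bg", tmp_path / "m.bg", 500) == track


class TestAnnotationIO:
    def make_annotation(self):
        genes = [
            GeneRecord("g1", "CDS", iv(100, 400, "+"), name="abc"),
            GeneRecord("g2", "tRNA", iv(600, 680, "-")),
            GeneRecord("g3", "pseudo", iv(700, 900, "+")),
        ]
        terms = [Terminator("t1", iv(450, 480, "+"))]
        return GenomeAnnotation(1000, chrom="chr", genes=genes,
                                terminators=terms)

    def test_round_trip(self, tmp_path):
        ann = self.make_annotation()
        write_annotation(ann, tmp_path / "a.gff3")
        back = read_annotation(tmp_path / "a.gff3")
        assert back.genome_length == 1000
        assert [(g.locus_tag, g.kind, g.interval) for g in back.genes] == \
            [(g.locus_tag, g.kind, g.interval) for g in ann.genes]
        assert back.genes[0].name == "abc"
        assert [(t.term_id, t.interval) for t in back.terminators] == \
            [(t.term_id, t.interval) for t in ann.terminators]

    def test_unknown_types_skipped(self, tmp_path):
        gff = ("##gff-version 3\n##sequence-region chr 1 1000\n"
               "chr\tx\tCDS\t10\t100\t.\t+\t.\tID=g1\n"
               "chr\tx\tregion\t1\t1000\t.\t+\t.\tID=weird\n")
        (tmp_path / "a.gff3").write_text(gff)
        ann = read_annotation(tmp_path / "a.gff3")
        assert len(ann.genes) == 1

    def test_empty_body_with_pragma(self, tmp_path):
        (tmp_path / "a.gff3").write_text(
            "##gff-version 3\n##sequence-region chr 1 1000\n")
        ann = read_annotation(tmp_path / "a.gff3")
        assert ann.genome_length == 1000 and len(ann.genes) == 0

    def test_duplicate_locus_tag_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenomeAnnotation(1000, genes=[
                GeneRecord("g1", "CDS", iv(1, 10, "+")),
                GeneRecord("g1", "CDS", iv(20, 30, "+"))])

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            GenomeAnnotation(100, genes=[
                GeneRecord("g1", "CDS", iv(50, 150, "+"))])


class TestTsvIO:
    def test_terminator_round_trip(self, tmp_path):
        terms = [Terminator("t1", iv(10, 40, "+")),
                 Terminator("t2", iv(100, 130, "-"))]
        write_terminators(terms, tmp_path / "t.tsv")
        assert read_terminators(tmp_path / "t.tsv") == terms

    def test_sample_sheet_round_trip(self, tmp_path):
        sheet = SampleSheet({"L-I": SampleInfo("I", "L", "rnaseq"),
                             "d-L-I": SampleInfo("I", "L", "drnaseq")})
        write_sample_sheet(sheet, tmp_path / "s.tsv")
        assert read_sample_sheet(tmp_path / "s.tsv").samples == sheet.samples

    def test_duplicate_triple_rejected(self):
        with pytest.raises(ValueError):
            SampleSheet({"a": SampleInfo("I", "L", "rnaseq"),
                         "b": SampleInfo("I", "L", "rnaseq")})
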