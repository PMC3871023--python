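"""Segmentation, UTR boundary rules and the ten-class feature taxonomy."""

import numpy as np
import pytest

from regulome.feature_annotator import (
    RnaFeature,
    annotate_features,
    call_3utrs,
    call_5utrs,
    call_ncrnas,
    classify_feature,
    read_feature_table,
    segment_transcribed,
    write_feature_table,
)
from regulome.genome_model import (
    CoverageTrack,
    GeneRecord,
    GenomeAnnotation,
    StrandedInterval,
    Terminator,
    antisense_overlap,
)
from regulome.tss_caller import TssRecord


def iv(start, end, strand="+"):
    return StrandedInterval("chr", start, end, strand)


def cov_track(L, plus_spans=(), minus_spans=()):
    t = CoverageTrack(L)
    for lo, hi in plus_spans:
        t.fwd[lo - 1:hi] = 10
    for lo, hi in minus_spans:
        t.rev[lo - 1:hi] = 10
    return t


def ann(genes=(), terminators=(), L=2000):
    return GenomeAnnotation(L, genes=list(genes),
                            terminators=list(terminators))


def supported_tss(pos, strand="+"):
    return TssRecord(pos, strand, 2.0, ("I", "II"), supported=True)


class TestSegmentation:
    def test_zero_coverage_empty(self):
        assert segment_transcribed(CoverageTrack(100)) == []

    def test_single_run(self):
        segs = segment_transcribed(cov_track(1000, [(100, 200)]))
        assert [s.interval for s in segs] == [iv(100, 200)]

    def test_single_zero_base_splits(self):
        t = cov_track(1000, [(100, 150), (152, 200)])
        segs = segment_transcribed(t)
        assert [s.interval for s in segs] == [iv(100, 150), iv(152, 200)]

    def test_run_length_oracle_on_random_tracks(self, rng):
        arr = (rng.random(500) < 0.4).astype(np.int64) * \
            rng.integers(1, 5, 500)
        t = CoverageTrack(500, arr.copy(), np.zeros(500, dtype=np.int64))
        segs = [s.interval for s in segment_transcribed(t)]
        # brute-force scan
        expected, start = [], None
        for i, v in enumerate(arr, 1):
            if v > 0 and start is None:
                start = i
            if v == 0 and start is not None:
                expected.append(iv(start, i - 1))
                start = None
        if start is not None:
            expected.append(iv(start, 500))
        assert segs == expected

    def test_strands_segmented_independently(self):
        t = cov_track(1000, [(100, 200)], [(150, 300)])
        segs = segment_transcribed(t)
        assert {s.interval.strand for s in segs} == {"+", "-"}


class TestCall5Utrs:
    def test_rise_gives_utr_length(self):
        gene = GeneRecord("g", "CDS", iv(300, 500))
        segs = segment_transcribed(cov_track(1000, [(183, 500)]))
        utrs = call_5utrs(segs, ann([gene]), [])
        assert [u.interval for u in utrs] == [iv(183, 299)]
        assert utrs[0].length == 117
        assert utrs[0].parent_gene == "g"

    def test_no_upstream_coverage_no_utr(self):
        gene = GeneRecord("g", "CDS", iv(300, 500))
        segs = segment_transcribed(cov_track(1000, [(300, 500)]))
        assert call_5utrs(segs, ann([gene]), []) == []

    def test_readthrough_masking_uses_supported_tss(self):
        up = GeneRecord("up", "CDS", iv(100, 200))
        gene = GeneRecord("g", "CDS", iv(300, 500))
        segs = segment_transcribed(cov_track(1000, [(50, 500)]))
        utrs = call_5utrs(segs, ann([up, gene]), [supported_tss(220)])
        by_gene = {u.parent_gene: u for u in utrs}
        assert by_gene["g"].interval == iv(220, 299)
        assert by_gene["g"].length == 80
        assert by_gene["g"].tss_link == 220

    def test_readthrough_without_tss_gives_no_utr(self):
        up = GeneRecord("up", "CDS", iv(100, 200))
        gene = GeneRecord("g", "CDS", iv(300, 500))
        segs = segment_transcribed(cov_track(1000, [(50, 500)]))
        utrs = call_5utrs(segs, ann([up, gene]), [])
        assert [u.parent_gene for u in utrs] == ["up"]

    def test_minus_strand_mirrored(self):
        gene = GeneRecord("g", "CDS", iv(300, 500, "-"))
        segs = segment_transcribed(cov_track(1000, (), [(300, 617)]))
        utrs = call_5utrs(segs, ann([gene]), [])
        assert [u.interval for u in utrs] == [iv(501, 617, "-")]
        assert utrs[0].length == 117


class TestCall3Utrs:
    def test_fall_with_terminator_at_end(self):
        gene = GeneRecord("g", "CDS", iv(300, 500))
        term = Terminator("t1", iv(746, 776))
        segs = segment_transcribed(cov_track(1000, [(300, 776)]))
        utrs, rt = call_3utrs(segs, ann([gene]), [term])
        assert [u.interval for u in utrs] == [iv(501, 776)]
        assert utrs[0].length == 276
        assert utrs[0].terminator_status == "at_terminator"
        assert rt == []

    def test_internal_terminator_370_upstream(self):
        gene = GeneRecord("g", "CDS", iv(300, 500))
        term = Terminator("t1", iv(600, 630))  # 3' end 370 nt before 1000
        segs = segment_transcribed(cov_track(1500, [(300, 1000)]))
        utrs, _ = call_3utrs(segs, ann([gene], L=1500), [term])
        assert utrs[0].terminator_status == "internal_terminator"

    @pytest.mark.parametrize("t3,status", [
        (952, "at_terminator"),        # 48 nt upstream of the end
        (951, "at_terminator"),        # 49 nt upstream: still within 50
        (950, "internal_terminator"),  # exactly 50 nt upstream
        (800, "internal_terminator"),
    ])
    def test_internal_terminator_distance_rule(self, t3, status):
        gene = GeneRecord("g", "CDS", iv(300, 500))
        term = Terminator("t1", iv(t3 - 30, t3))
        segs = segment_transcribed(cov_track(1500, [(300, 1000)]))
        utrs, _ = call_3utrs(segs, ann([gene], L=1500), [term])
        assert utrs[0].terminator_status == status

    def test_no_downstream_coverage_no_utr(self):
        gene = GeneRecord("g", "CDS", iv(300, 500))
        segs = segment_transcribed(cov_track(1000, [(300, 500)]))
        utrs, _ = call_3utrs(segs, ann([gene]), [])
        assert utrs == []

    def test_readthrough_capped_at_gap_terminator(self):
        g1 = GeneRecord("g1", "CDS", iv(300, 500))
        g2 = GeneRecord("g2", "CDS", iv(900, 1100))
        term = Terminator("t1", iv(570, 600))
        segs = segment_transcribed(cov_track(1500, [(300, 1100)]))
        utrs, rt = call_3utrs(segs, ann([g1, g2], L=1500), [term])
        by_gene = {u.parent_gene: u for u in utrs}
        assert by_gene["g1"].interval == iv(501, 600)
        assert by_gene["g1"].terminator_status == "at_terminator"
        # the remaining gap becomes a read-through candidate
        assert [r.interval for r in rt] == [iv(601, 899)]

    def test_readthrough_without_gap_terminator_no_utr(self):
        g1 = GeneRecord("g1", "CDS", iv(300, 500))
        g2 = GeneRecord("g2", "CDS", iv(900, 1100))
        segs = segment_transcribed(cov_track(1500, [(300, 1100)]))
        utrs, rt = call_3utrs(segs, ann([g1, g2], L=1500), [])
        assert "g1" not in {u.parent_gene for u in utrs}
        assert rt == []

    def test_readthrough_flag_needs_length_over_threshold(self):
        gene = GeneRecord("g", "CDS", iv(300, 500))
        term = Terminator("t1", iv(570, 600))
        segs = segment_transcribed(cov_track(3000, [(300, 2000)]))
        utrs, _ = call_3utrs(segs, ann([gene], L=3000), [term])
        assert utrs[0].terminator_status == "internal_terminator"
        assert utrs[0].readthrough_flag  # 1500 nt > 1000


class TestClassification:
    def base_ann(self):
        genes = [GeneRecord("gA", "CDS", iv(500, 1000, "+")),
                 GeneRecord("gB", "CDS", iv(1100, 1500, "+"))]
        return ann(genes, L=3000)

    def utr(self, fid, interval, cls, parent="gA"):
        return RnaFeature(fid, interval, rna_class=cls, parent_gene=parent)

    @pytest.mark.parametrize("overlap,expected", [
        (100, "5'UTR"),    # rule is strictly "exceeds 100 nt"
        (101, "A_5'UTR"),
    ])
    def test_utr_antisense_boundary(self, overlap, expected):
        genes = [GeneRecord("gA", "CDS", iv(500, 1000, "+")),
                 GeneRecord("opp", "CDS", iv(300, 300 + overlap - 1, "-"))]
        a = ann(genes, L=3000)
        utr = self.utr("u", iv(300, 499), "5'UTR")
        assert antisense_overlap(utr.interval,
                                 a.gene("opp").interval) == overlap
        out = classify_feature(utr, a, [utr])
        assert out.rna_class == expected

    def test_ncrna_wholly_inside_gene_is_a_i(self):
        a = self.base_ann()
        feat = RnaFeature("n", iv(600, 800, "-"))
        assert classify_feature(feat, a, []).rna_class == "A_I"

    def test_ncrna_spanning_two_genes_is_a_misc(self):
        a = self.base_ann()
        feat = RnaFeature("n", iv(900, 1200, "-"))
        assert classify_feature(feat, a, []).rna_class == "A_misc"

    def test_ncrna_partially_antisense_is_a_misc(self):
        a = self.base_ann()
        feat = RnaFeature("n", iv(400, 700, "-"))  # sticks out of gA
        assert classify_feature(feat, a, []).rna_class == "A_misc"

    def test_intergenic_ncrna_is_indep(self):
        a = self.base_ann()
        feat = RnaFeature("n", iv(2000, 2200, "-"))
        out = classify_feature(feat, a, [])
        assert out.rna_class == "indep" and out.antisense_targets == ()

    def test_ncrna_solely_over_utr(self):
        a = self.base_ann()
        utr5 = self.utr("u5", iv(300, 499), "5'UTR")
        utr3 = self.utr("u3", iv(1501, 1800), "3'UTR", parent="gB")
        f5 = RnaFeature("n5", iv(350, 450, "-"))
        f3 = RnaFeature("n3", iv(1600, 1700, "-"))
        assert classify_feature(f5, a, [utr5, utr3]).rna_class == "A_5"
        assert classify_feature(f3, a, [utr5, utr3]).rna_class == "A_3"

    def test_readthrough_candidate_needs_antisense(self):
        a = self.base_ann()
        with_target = RnaFeature("r", iv(600, 700, "-"),
                                 is_readthrough_segment=True)
        without = RnaFeature("r2", iv(2000, 2100, "-"),
                             is_readthrough_segment=True)
        assert classify_feature(with_target, a, []).rna_class == "A_rt"
        assert classify_feature(without, a, []).rna_class is None

    def test_call_ncrnas_excludes_same_strand_overlap(self):
        a = self.base_ann()
        segs = segment_transcribed(
            cov_track(3000, [(600, 800)], [(2000, 2200)]))
        cands = call_ncrnas(segs, a, [])
        assert [c.interval for c in cands] == [iv(2000, 2200, "-")]


def oracle_classify(feat, genes, utrs):
    """Independent per-base classifier for candidate ncRNAs."""
    bases = set(range(feat.interval.start, feat.interval.end + 1))
    strand = feat.interval.strand
    gene_bases = {}
    for g in genes:
        if g.strand != strand and g.kind == "CDS":
            hit = bases & set(range(g.interval.start, g.interval.end + 1))
            if hit:
                gene_bases[g.locus_tag] = \
                    set(range(g.interval.start, g.interval.end + 1))
    utr_bases = {"5": {}, "3": {}}
    for u in utrs:
        if u.interval.strand != strand:
            hit = bases & set(range(u.interval.start, u.interval.end + 1))
            if hit:
                kind = "5" if "5" in u.rna_class else "3"
                utr_bases[kind][u.feature_id] = \
                    set(range(u.interval.start, u.interval.end + 1))
    n5, n3 = len(utr_bases["5"]), len(utr_bases["3"])
    if not gene_bases and not n5 and not n3:
        return "indep"
    if len(gene_bases) == 1 and not n5 and not n3 \
            and bases <= next(iter(gene_bases.values())):
        return "A_I"
    if not gene_bases and n5 == 1 and not n3 \
            and bases <= next(iter(utr_bases["5"].values())):
        return "A_5"
    if not gene_bases and not n5 and n3 == 1 \
            and bases <= next(iter(utr_bases["3"].values())):
        return "A_3"
    return "A_misc"


class TestOracleEquivalence:
    def test_thousand_randomized_features(self, rng):
        L = 20_000
        genes, utrs = [], []
        pos = 200
        i = 0
        while pos < L - 1500:
            strand = "+" if rng.random() < 0.5 else "-"
            glen = int(rng.integers(200, 900))
            g = GeneRecord(f"g{i}", "CDS", iv(pos, pos + glen - 1, strand))
            genes.append(g)
            if rng.random() < 0.7:  # attach UTRs to some genes
                u5len = int(rng.integers(20, 200))
                u3len = int(rng.integers(20, 300))
                if strand == "+":
                    utrs.append(RnaFeature(f"u5_{i}",
                                           iv(pos - u5len, pos - 1, "+"),
                                           rna_class="5'UTR"))
                    utrs.append(RnaFeature(
                        f"u3_{i}", iv(pos + glen, pos + glen + u3len - 1, "+"),
                        rna_class="3'UTR"))
                else:
                    utrs.append(RnaFeature(
                        f"u5_{i}", iv(pos + glen, pos + glen + u5len - 1, "-"),
                        rna_class="5'UTR"))
                    utrs.append(RnaFeature(f"u3_{i}",
                                           iv(pos - u3len, pos - 1, "-"),
                                           rna_class="3'UTR"))
            pos += glen + int(rng.integers(350, 700))
            i += 1
        annotation = ann(genes, L=L)
        mismatches = []
        for j in range(1200):
            start = int(rng.integers(1, L - 600))
            span = int(rng.integers(30, 600))
            strand = "+" if rng.random() < 0.5 else "-"
            feat = RnaFeature(f"c{j}", iv(start, start + span - 1, strand))
            got = classify_feature(feat, annotation, utrs).rna_class
            want = oracle_classify(feat, genes, utrs)
            if got != want:
                mismatches.append((feat.interval, got, want))
        assert not mismatches, mismatches[:5]


class TestTableIO:
    def test_paper_style_round_trip(self):
        feats = [
            RnaFeature("RF0001", iv(100, 300, "+"), rna_class="indep"),
            RnaFeature("RF0002", iv(500, 900, "-"), rna_class="A_I",
                       antisense_targets=(("gX", 250),)),
        ]
        import io, tempfile, os
        with tempfile.TemporaryDirectory() as d:
            path = os.path.join(d, "features.tsv")
            write_feature_table(feats, path)
            lines = open(path).read().splitlines()
            # minus-strand row printed with start > stop
            assert lines[2].split("\t")[1:4] == ["900", "500", "401"]
            back = read_feature_table(path)
        assert [(f.feature_id, f.interval, f.rna_class, f.antisense_targets)
                for f in back] == \
            [(f.feature_id, f.interval, f.rna_class, f.antisense_targets)
             for f in feats]


class TestEndToEndRecovery:
    def test_planted_classes_and_boundaries_recovered(self, noise_free_run):
        res = noise_free_run
        truth = res.truth
        called = {(f.interval.start, f.interval.end, f.strand): f.rna_class
                  for f in res.features}
        for pf in truth.planted_features:
            key = (pf.interval.start, pf.interval.end, pf.interval.strand)
            assert key in called, (pf.feature_id, pf.rna_class)
            assert called[key] == pf.rna_class, pf.feature_id

    def test_no_spurious_features(self, noise_free_run):
        res = noise_free_run
        assert len(res.features) == len(res.truth.planted_features)
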