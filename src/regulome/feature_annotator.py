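"""Transcript-feature discovery and the ten-class RNA feature taxonomy.

Pooled strand-specific coverage is segmented into maximal runs of nonzero
activity.  Genes whose start/stop codons fall inside a segment receive
5'/3'UTRs bounded by the rise from / fall to zero coverage; segments clear
of same-strand genes and UTRs become ncRNA candidates.  Every feature is
then classified:

mRNA-bound classes
    ``5'UTR`` / ``3'UTR``; ``A_5'UTR`` / ``A_3'UTR`` when the UTR overlaps
    an opposite-strand gene by more than 100 nt; ``A_rt`` for an
    intergenic read-through region (past a leaky terminator, before the
    next transcript) antisense to a gene.
ncRNA classes
    ``indep`` (no antisense partner), ``A_I`` (wholly antisense within one
    gene body), ``A_5`` / ``A_3`` (wholly antisense within a 5'/3'UTR),
    ``A_misc`` (antisense to more than one gene, or partially antisense).

Read-through handling: when continuous coverage runs from one gene into a
downstream same-strand gene, the upstream 3'UTR is capped at the intrinsic
terminator inside the gap (no terminator - no assignable 3'UTR), and the
remaining gap region becomes an ``A_rt`` candidate.  Symmetrically, a
5'UTR masked by upstream read-through is bounded by a supported TSS in the
intergenic gap, keeping the longest supportable UTR in both directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_model import (
    CoverageTrack,
    GeneRecord,
    GenomeAnnotation,
    MINUS,
    PLUS,
    StrandedInterval,
    Terminator,
    antisense_overlap,
    sense_overlap,
    span_overlap,
)
from .tss_caller import TssRecord

logger = logging.getLogger("regulome")

RNA_CLASSES = ("5'UTR", "3'UTR", "A_5'UTR", "A_3'UTR", "A_rt",
               "A_5", "A_3", "A_I", "A_misc", "indep")
_UTR5_CLASSES = ("5'UTR", "A_5'UTR")
_UTR3_CLASSES = ("3'UTR", "A_3'UTR")


@dataclass(frozen=True)
class TranscribedSegment:
    """A maximal run of strictly positive pooled coverage on one strand."""

    interval: StrandedInterval
    max_coverage: int
    mean_coverage: float


@dataclass
class RnaFeature:
    feature_id: str
    interval: StrandedInterval
    rna_class: str | None = None
    parent_gene: str | None = None
    antisense_targets: tuple[tuple[str, int], ...] = ()
    tss_link: int | None = None
    terminator_status: str = "none"  # at_terminator | internal_terminator | none
    readthrough_flag: bool = False
    orf_flag: bool = False
    is_readthrough_segment: bool = False

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        return self.interval.length


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_transcribed(pooled: CoverageTrack, chrom: str = "chr"
                        ) -> list[TranscribedSegment]:
    """Maximal nonzero-coverage runs per strand; one zero base ends a run."""
    out = []
    for strand in (PLUS, MINUS):
        arr = pooled.activity(strand)
        pos = arr > 0
        if not pos.any():
            continue
        idx = np.flatnonzero(pos)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [len(idx) - 1]))
        for rs, re in zip(run_starts, run_ends):
            lo, hi = int(idx[rs]) + 1, int(idx[re]) + 1
            chunk = arr[lo - 1:hi]
            out.append(TranscribedSegment(
                StrandedInterval(chrom, lo, hi, strand),
                int(chunk.max()), float(chunk.mean())))
    out.sort(key=lambda s: (s.interval.start, s.interval.strand))
    return out


def split_by_abundance(segments: Sequence[TranscribedSegment],
                       pooled: CoverageTrack, factor: float = 10.0,
                       window: int = 50) -> list[TranscribedSegment]:
    """Opt-in splitter for abundance contrast inside one segment.

    A segment is cut between adjacent ``window``-sized sub-windows whose
    mean coverages differ by more than ``factor``; this mechanizes the
    manual separation of highly abundant transcripts embedded in weaker
    ones.  Off by default in the pipeline.
    """
    out = []
    for seg in segments:
        iv = seg.interval
        arr = pooled.activity(iv.strand)[iv.start - 1:iv.end].astype(float)
        cuts = [0]
        n_win = len(arr) // window
        for w in range(1, n_win):
            a = arr[(w - 1) * window:w * window].mean()
            b = arr[w * window:(w + 1) * window].mean()
            lo, hi = min(a, b), max(a, b)
            if lo > 0 and hi / lo > factor:
                cuts.append(w * window)
        cuts.append(len(arr))
        for lo_off, hi_off in zip(cuts, cuts[1:]):
            chunk = arr[lo_off:hi_off]
            out.append(TranscribedSegment(
                StrandedInterval(iv.chrom, iv.start + lo_off,
                                 iv.start + hi_off - 1, iv.strand),
                int(chunk.max()), float(chunk.mean())))
    out.sort(key=lambda s: (s.interval.start, s.interval.strand))
    return out


# ---------------------------------------------------------------------------
# UTR calling
# ---------------------------------------------------------------------------

def _segment_containing(segments: Sequence[TranscribedSegment], strand: str,
                        pos: int) -> TranscribedSegment | None:
    for seg in segments:
        if seg.interval.strand == strand and seg.interval.contains(pos):
            return seg
    return None


def _coding_genes(annotation: GenomeAnnotation) -> list[GeneRecord]:
    return [g for g in annotation.genes if g.kind == "CDS"]


def call_5utrs(segments: Sequence[TranscribedSegment],
               annotation: GenomeAnnotation,
               tss: Sequence[TssRecord]) -> list[RnaFeature]:
    """5'UTRs: from the segment's rise from zero (or a supported TSS when
    upstream read-through masks the rise) to the base before the start
    codon.  The longest supportable candidate is kept."""
    supported = [t for t in tss if t.supported]
    out = []
    for gene in _coding_genes(annotation):
        strand = gene.strand
        start_codon = gene.interval.five_prime
        seg = _segment_containing(segments, strand, start_codon)
        if seg is None:
            continue
        if strand == PLUS:
            lo, hi = seg.interval.start, gene.interval.start - 1
        else:
            lo, hi = gene.interval.end + 1, seg.interval.end
        if lo > hi:
            continue  # zero-length 5'UTR
        region = StrandedInterval(gene.interval.chrom, lo, hi, strand)
        upstream = [g for g in annotation.genes
                    if g.strand == strand and g.locus_tag != gene.locus_tag
                    and span_overlap(g.interval, region) > 0]
        if not upstream:
            utr_iv = region
        else:
            # read-through from an upstream gene: fall back to a supported
            # TSS in the intergenic gap
            if strand == PLUS:
                gap_lo = max(g.interval.end for g in upstream) + 1
                gap_hi = gene.interval.start - 1
                cands = [t.position for t in supported
                         if t.strand == strand and gap_lo <= t.position <= gap_hi]
                if not cands:
                    continue
                utr_iv = StrandedInterval(region.chrom, min(cands), gap_hi,
                                          strand)
            else:
                gap_hi = min(g.interval.start for g in upstream) - 1
                gap_lo = gene.interval.end + 1
                cands = [t.position for t in supported
                         if t.strand == strand and gap_lo <= t.position <= gap_hi]
                if not cands:
                    continue
                utr_iv = StrandedInterval(region.chrom, gap_lo, max(cands),
                                          strand)
        link = next((t.position for t in supported
                     if t.strand == strand
                     and t.position == utr_iv.five_prime), None)
        out.append(RnaFeature(f"utr5_{gene.locus_tag}", utr_iv,
                              rna_class="5'UTR", parent_gene=gene.locus_tag,
                              tss_link=link))
    return out


def call_3utrs(segments: Sequence[TranscribedSegment],
               annotation: GenomeAnnotation,
               terminators: Sequence[Terminator],
               utr5s: Sequence[RnaFeature] = (),
               internal_terminator_distance: int = 50,
               readthrough_length: int = 1000
               ) -> tuple[list[RnaFeature], list[RnaFeature]]:
    """3'UTRs plus intergenic read-through candidates.

    Returns ``(utr3s, readthrough_candidates)``.  A gene whose segment
    runs into a downstream same-strand gene gets its 3'UTR capped at the
    intrinsic terminator inside the gap (none - no 3'UTR); the region from
    that terminator to the downstream transcript's 5' boundary becomes a
    read-through candidate, later kept only if antisense to a gene.
    """
    utr5_by_gene = {u.parent_gene: u for u in utr5s}
    out: list[RnaFeature] = []
    rt: list[RnaFeature] = []
    for gene in _coding_genes(annotation):
        strand = gene.strand
        stop_codon = gene.interval.three_prime
        seg = _segment_containing(segments, strand, stop_codon)
        if seg is None:
            continue
        chrom = gene.interval.chrom
        if strand == PLUS:
            lo, hi = gene.interval.end + 1, seg.interval.end
        else:
            lo, hi = seg.interval.start, gene.interval.start - 1
        if lo > hi:
            continue  # no coverage beyond the stop codon
        region = StrandedInterval(chrom, lo, hi, strand)
        downstream = [g for g in annotation.genes
                      if g.strand == strand and g.locus_tag != gene.locus_tag
                      and span_overlap(g.interval, region) > 0]
        rt_piece = None
        if not downstream:
            utr_iv = region
        else:
            if strand == PLUS:
                gap_hi = min(g.interval.start for g in downstream) - 1
                gap = StrandedInterval(chrom, lo, gap_hi, strand) \
                    if lo <= gap_hi else None
            else:
                gap_lo = max(g.interval.end for g in downstream) + 1
                gap = StrandedInterval(chrom, gap_lo, hi, strand) \
                    if gap_lo <= hi else None
            term = _best_gap_terminator(terminators, gap) if gap else None
            if term is None:
                continue  # read-through with no separating terminator
            t3 = term.interval.three_prime
            if strand == PLUS:
                utr_iv = StrandedInterval(chrom, lo, t3, strand)
                next_start = _next_transcript_start(
                    downstream, utr5_by_gene, strand)
                if t3 + 1 <= next_start - 1:
                    rt_piece = StrandedInterval(chrom, t3 + 1,
                                                next_start - 1, strand)
            else:
                utr_iv = StrandedInterval(chrom, t3, hi, strand)
                next_start = _next_transcript_start(
                    downstream, utr5_by_gene, strand)
                if next_start + 1 <= t3 - 1:
                    rt_piece = StrandedInterval(chrom, next_start + 1,
                                                t3 - 1, strand)
        status, flag = _terminator_status(
            terminators, utr_iv, internal_terminator_distance,
            readthrough_length)
        out.append(RnaFeature(f"utr3_{gene.locus_tag}", utr_iv,
                              rna_class="3'UTR", parent_gene=gene.locus_tag,
                              terminator_status=status,
                              readthrough_flag=flag))
        if rt_piece is not None:
            rt.append(RnaFeature(f"rt_{gene.locus_tag}", rt_piece,
                                 is_readthrough_segment=True))
    return out, rt


def _best_gap_terminator(terminators: Sequence[Terminator],
                         gap: StrandedInterval) -> Terminator | None:
    """Most-downstream same-strand terminator fully inside the gap."""
    inside = [t for t in terminators
              if t.interval.strand == gap.strand
              and gap.contains_interval(t.interval)]
    if not inside:
        return None
    if gap.strand == PLUS:
        return max(inside, key=lambda t: t.interval.end)
    return min(inside, key=lambda t: t.interval.start)


def _next_transcript_start(downstream: Sequence[GeneRecord],
                           utr5_by_gene: Mapping[str, RnaFeature],
                           strand: str) -> int:
    """5' boundary of the nearest downstream gene's transcript (its 5'UTR
    start if one was called, else its start codon)."""
    if strand == PLUS:
        g = min(downstream, key=lambda g: g.interval.start)
    else:
        g = max(downstream, key=lambda g: g.interval.end)
    utr = utr5_by_gene.get(g.locus_tag)
    if utr is not None:
        return utr.interval.five_prime
    return g.interval.five_prime


def _terminator_status(terminators: Sequence[Terminator],
                       utr_iv: StrandedInterval, near: int,
                       readthrough_length: int) -> tuple[str, bool]:
    t3s = [t.interval.three_prime for t in terminators
           if t.interval.strand == utr_iv.strand
           and utr_iv.contains(t.interval.three_prime)]
    if not t3s:
        return "none", False
    transcript_end = utr_iv.three_prime
    dists = [abs(transcript_end - t3) for t3 in t3s]
    if min(dists) < near:
        return "at_terminator", False
    return "internal_terminator", utr_iv.length > readthrough_length


# ---------------------------------------------------------------------------
# ncRNA candidates
# ---------------------------------------------------------------------------

def call_ncrnas(segments: Sequence[TranscribedSegment],
                annotation: GenomeAnnotation,
                utrs: Sequence[RnaFeature],
                orf_min_codons: int = 50,
                sequence: str | None = None) -> list[RnaFeature]:
    """Segments clear of same-strand genes and UTRs, boundaries at the
    first/last nonzero base.  Candidates containing a same-strand ORF of
    at least ``orf_min_codons`` are flagged, not dropped."""
    out = []
    for seg in segments:
        iv = seg.interval
        if any(sense_overlap(iv, g.interval) for g in annotation.genes):
            continue
        if any(sense_overlap(iv, u.interval) for u in utrs):
            continue
        feat = RnaFeature(f"nc_{iv.start}_{iv.strand}", iv)
        if sequence is not None and _has_orf(sequence, iv, orf_min_codons):
            feat.orf_flag = True
        out.append(feat)
    return out


_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGT", "TGCA")


def _has_orf(sequence: str, iv: StrandedInterval, min_codons: int) -> bool:
    sub = sequence[iv.start - 1:iv.end].upper()
    if iv.strand == MINUS:
        sub = sub.translate(_COMP)[::-1]
    for frame in range(3):
        i = frame
        while i + 3 <= len(sub):
            if sub[i:i + 3] == "ATG":
                j = i + 3
                while j + 3 <= len(sub) and sub[j:j + 3] not in _STOPS:
                    j += 3
                if j + 3 <= len(sub) and (j - i) // 3 >= min_codons:
                    return True
                i = j
            i += 3
    return False


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_feature(feature: RnaFeature, annotation: GenomeAnnotation,
                     utrs: Sequence[RnaFeature],
                     utr_antisense_min: int = 100,
                     ncrna_antisense_min: int = 1) -> RnaFeature:
    """Assign the final RNA class and record antisense targets.

    UTRs become ``A_5'UTR``/``A_3'UTR`` when their overlap to a single
    opposite gene exceeds ``utr_antisense_min`` (strict).  Read-through
    candidates become ``A_rt`` iff antisense to a gene, else class None
    (caller drops them).  ncRNA candidates follow the containment rules in
    the module docstring.
    """
    iv = feature.interval
    gene_hits = [(g.locus_tag, antisense_overlap(iv, g.interval), g.interval)
                 for g in _coding_genes(annotation)
                 if antisense_overlap(iv, g.interval) >= ncrna_antisense_min]
    targets = tuple((tag, ov) for tag, ov, _ in gene_hits)

    if feature.rna_class in _UTR5_CLASSES + _UTR3_CLASSES:
        base = "5'UTR" if feature.rna_class in _UTR5_CLASSES else "3'UTR"
        is_anti = any(ov > utr_antisense_min for _, ov, _ in gene_hits)
        cls = f"A_{base}" if is_anti else base
        return replace_feature(feature, cls, targets)

    if feature.is_readthrough_segment:
        if gene_hits:
            return replace_feature(feature, "A_rt", targets)
        return replace_feature(feature, None, targets)

    # ncRNA candidate
    utr5_hits = [(u.feature_id, antisense_overlap(iv, u.interval), u.interval)
                 for u in utrs if u.rna_class in _UTR5_CLASSES
                 and antisense_overlap(iv, u.interval) >= ncrna_antisense_min]
    utr3_hits = [(u.feature_id, antisense_overlap(iv, u.interval), u.interval)
                 for u in utrs if u.rna_class in _UTR3_CLASSES
                 and antisense_overlap(iv, u.interval) >= ncrna_antisense_min]
    all_targets = targets + tuple((fid, ov) for fid, ov, _ in utr5_hits
                                  ) + tuple((fid, ov) for fid, ov, _ in utr3_hits)

    if not gene_hits and not utr5_hits and not utr3_hits:
        return replace_feature(feature, "indep", ())
    if (len(gene_hits) == 1 and not utr5_hits and not utr3_hits
            and gene_hits[0][2].contains_interval(iv)):
        return replace_feature(feature, "A_I", targets)
    if (not gene_hits and len(utr5_hits) == 1 and not utr3_hits
            and utr5_hits[0][2].contains_interval(iv)):
        return replace_feature(feature, "A_5", all_targets)
    if (not gene_hits and not utr5_hits and len(utr3_hits) == 1
            and utr3_hits[0][2].contains_interval(iv)):
        return replace_feature(feature, "A_3", all_targets)
    return replace_feature(feature, "A_misc", all_targets)


def replace_feature(feature: RnaFeature, rna_class: str | None,
                    targets: tuple[tuple[str, int], ...]) -> RnaFeature:
    feature.rna_class = rna_class
    feature.antisense_targets = targets
    return feature


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def annotate_features(pooled: CoverageTrack, annotation: GenomeAnnotation,
                      tss: Sequence[TssRecord],
                      orf_min_codons: int = 50,
                      sequence: str | None = None,
                      utr_antisense_min: int = 100,
                      ncrna_antisense_min: int = 1,
                      internal_terminator_distance: int = 50,
                      readthrough_length: int = 1000,
                      abundance_split_factor: float | None = None
                      ) -> list[RnaFeature]:
    """Full feature discovery on pooled coverage; returns classified
    features with stable genome-ordered ids (RF0001..)."""
    segments = segment_transcribed(pooled, annotation.chrom)
    if abundance_split_factor is not None:
        segments = split_by_abundance(segments, pooled,
                                      abundance_split_factor)
    utr5s = call_5utrs(segments, annotation, tss)
    utr3s, rt_cands = call_3utrs(
        segments, annotation, annotation.terminators, utr5s,
        internal_terminator_distance, readthrough_length)
    utrs = utr5s + utr3s
    ncrnas = call_ncrnas(segments, annotation, utrs, orf_min_codons, sequence)

    features: list[RnaFeature] = []
    for u in utrs:
        features.append(classify_feature(u, annotation, utrs,
                                         utr_antisense_min,
                                         ncrna_antisense_min))
    for cand in rt_cands + ncrnas:
        feat = classify_feature(cand, annotation, utrs, utr_antisense_min,
                                ncrna_antisense_min)
        if feat.rna_class is None:
            logger.info("dropping non-antisense read-through segment %s",
                        feat.interval)
            continue
        features.append(feat)
    features.sort(key=lambda f: (f.interval.start, f.interval.strand))
    for i, f in enumerate(features, 1):
        f.feature_id = f"RF{i:04d}"
    return features


def class_counts(features: Sequence[RnaFeature]) -> dict[str, int]:
    counts = {c: 0 for c in RNA_CLASSES}
    for f in features:
        if f.rna_class:
            counts[f.rna_class] += 1
    return counts


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_feature_gff3(features: Sequence[RnaFeature],
                       annotation: GenomeAnnotation,
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {annotation.chrom} 1 "
                 f"{annotation.genome_length}\n")
        for f in features:
            iv = f.interval
            attrs = [f"ID={f.feature_id}", f"rna_class={f.rna_class}"]
            if f.parent_gene:
                attrs.append(f"parent_gene={f.parent_gene}")
            if f.antisense_targets:
                tgt = ",".join(f"{t}:{ov}" for t, ov in f.antisense_targets)
                attrs.append(f"antisense_targets={tgt}")
            if f.terminator_status != "none":
                attrs.append(f"terminator_status={f.terminator_status}")
            if f.readthrough_flag:
                attrs.append("readthrough=1")
            if f.orf_flag:
                attrs.append("orf_flag=1")
            fh.write(f"{iv.chrom}\tregulome\ttranscript\t{iv.start}\t"
                     f"{iv.end}\t.\t{iv.strand}\t.\t{';'.join(attrs)}\n")


def write_feature_table(features: Sequence[RnaFeature], path: str | Path,
                        npkm_max: Mapping[str, float] | None = None) -> None:
    """Publication-style TSV: start > stop encodes the minus strand."""
    with open(path, "w") as fh:
        fh.write("feature\tstart\tstop\tlength\tclass\tparent\t"
                 "antisense_targets\tnpkm_max\n")
        for f in features:
            start, stop = f.interval.to_printed()
            tgt = ",".join(f"{t}:{ov}" for t, ov in f.antisense_targets)
            nm = "" if npkm_max is None else \
                f"{npkm_max.get(f.feature_id, 0.0):.1f}"
            fh.write(f"{f.feature_id}\t{start}\t{stop}\t{f.length}\t"
                     f"{f.rna_class}\t{f.parent_gene or ''}\t{tgt}\t{nm}\n")


def read_feature_table(path: str | Path, chrom: str = "chr"
                       ) -> list[RnaFeature]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            fid, start, stop, length, cls, parent, tgt, _nm = \
                line.rstrip("\n").split("\t")
            iv = StrandedInterval.from_printed(chrom, int(start), int(stop))
            targets = tuple((p.split(":")[0], int(p.split(":")[1]))
                            for p in tgt.split(",") if p)
            out.append(RnaFeature(fid, iv, rna_class=cls,
                                  parent_gene=parent or None,
                                  antisense_targets=targets))
    return out
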