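"""Operon prediction from pooled coverage, terminators and supported TSS.

Same-strand genes adjacent in genome order are split into separate
transcription units when, in priority order:

(a) a base of zero pooled coverage lies in the intergenic gap;
(b) an intrinsic terminator lies fully within the gap;
(c) a supported TSS lies in the gap (or in the upstream gene's 3' half)
    and the two genes' pooled NPKMs differ by more than ``split_ratio``.

Otherwise the pair is joined.  The result is a partition of all genes into
operons; monocistronic operons are allowed, and the default ``split_ratio``
of 4 keeps one fold-change scale with the ln 4 TSS step threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .genome_model import (
    CoverageTrack,
    GeneRecord,
    GenomeAnnotation,
    MINUS,
    PLUS,
    StrandedInterval,
    Terminator,
)
from .quantify import npkm_interval
from .tss_caller import TssRecord


@dataclass(frozen=True)
class Operon:
    operon_id: str
    strand: str
    genes: tuple[str, ...]  # locus tags in transcription order
    primary_tss: int | None = None
    terminal_terminator: str | None = None


def predict_operons(annotation: GenomeAnnotation, pooled: CoverageTrack,
                    tss: Sequence[TssRecord], split_ratio: float = 4.0,
                    join_veto: Sequence[tuple[str, str]] = ()
                    ) -> list[Operon]:
    """Partition all genes into operons.

    ``join_veto`` optionally lists (upstream_locus, downstream_locus) pairs
    from external operon evidence that force a split.
    """
    supported = [t for t in tss if t.supported]
    veto = set(join_veto)
    G = pooled.total_activity()
    operons: list[list[GeneRecord]] = []
    for strand in (PLUS, MINUS):
        genes = sorted(annotation.genes_on(strand),
                       key=lambda g: g.interval.start)
        if strand == MINUS:
            genes = genes[::-1]  # transcription order
        current: list[GeneRecord] = []
        for gene in genes:
            if not current:
                current = [gene]
                continue
            up = current[-1]
            if _split_pair(up, gene, annotation, pooled, supported,
                           split_ratio, G) or \
                    (up.locus_tag, gene.locus_tag) in veto:
                operons.append(current)
                current = [gene]
            else:
                current.append(gene)
        if current:
            operons.append(current)

    operons.sort(key=lambda ops: min(g.interval.start for g in ops))
    out = []
    for i, genes in enumerate(operons, 1):
        strand = genes[0].strand
        out.append(Operon(
            f"op{i:04d}", strand, tuple(g.locus_tag for g in genes),
            primary_tss=_primary_tss(genes[0], supported),
            terminal_terminator=_terminal_terminator(
                genes[-1], annotation.terminators)))
    return out


def _gap(up: GeneRecord, down: GeneRecord) -> StrandedInterval | None:
    """Intergenic gap between a pair in transcription order, or None."""
    strand = up.strand
    if strand == PLUS:
        lo, hi = up.interval.end + 1, down.interval.start - 1
    else:
        lo, hi = down.interval.end + 1, up.interval.start - 1
    if lo > hi:
        return None
    return StrandedInterval(up.interval.chrom, lo, hi, strand)


def _split_pair(up: GeneRecord, down: GeneRecord,
                annotation: GenomeAnnotation, pooled: CoverageTrack,
                supported: Sequence[TssRecord], split_ratio: float,
                G: int) -> bool:
    gap = _gap(up, down)
    strand = up.strand
    # (a) interrupted coverage in the gap
    if gap is not None:
        cov = pooled.activity(strand)[gap.start - 1:gap.end]
        if (cov == 0).any():
            return True
        # (b) terminator fully within the gap
        for t in annotation.terminators:
            if t.interval.strand == strand and \
                    gap.contains_interval(t.interval):
                return True
    # (c) internal supported TSS plus a distinct expression shift
    tss_zone = _tss_zone(up, gap)
    has_tss = any(t.strand == strand and tss_zone.contains(t.position)
                  for t in supported)
    if not has_tss:
        return False
    a = npkm_interval(pooled, up.interval, G)
    b = npkm_interval(pooled, down.interval, G)
    if a == 0 or b == 0:
        return a != b
    ratio = max(a / b, b / a)
    return ratio > split_ratio


def _tss_zone(up: GeneRecord, gap: StrandedInterval | None
              ) -> StrandedInterval:
    """The gap plus the upstream gene's 3' half."""
    iv = up.interval
    mid = iv.start + iv.length // 2
    if up.strand == PLUS:
        hi = gap.end if gap is not None else iv.end
        return StrandedInterval(iv.chrom, mid, hi, up.strand)
    lo = gap.start if gap is not None else iv.start
    return StrandedInterval(iv.chrom, lo, iv.start + iv.length // 2,
                            up.strand)


def _primary_tss(first_gene: GeneRecord, supported: Sequence[TssRecord],
                 window: int = 500) -> int | None:
    iv = first_gene.interval
    cands = []
    for t in supported:
        if t.strand != first_gene.strand:
            continue
        if first_gene.strand == PLUS and \
                iv.start - window <= t.position < iv.start:
            cands.append(t.position)
        if first_gene.strand == MINUS and \
                iv.end < t.position <= iv.end + window:
            cands.append(t.position)
    if not cands:
        return None
    # nearest TSS upstream of the start codon
    return max(cands) if first_gene.strand == PLUS else min(cands)


def _terminal_terminator(last_gene: GeneRecord,
                         terminators: Sequence[Terminator],
                         window: int = 500) -> str | None:
    iv = last_gene.interval
    cands = []
    for t in terminators:
        if t.interval.strand != last_gene.strand:
            continue
        t3 = t.interval.three_prime
        if last_gene.strand == PLUS and iv.end < t3 <= iv.end + window:
            cands.append((t3, t.term_id))
        if last_gene.strand == MINUS and iv.start - window <= t3 < iv.start:
            cands.append((-t3, t.term_id))
    if not cands:
        return None
    return min(cands)[1]


def operons_to_partition(operons: Sequence[Operon]) -> dict[str, int]:
    """locus_tag -> operon index labeling (for agreement metrics)."""
    labels = {}
    for i, op in enumerate(operons):
        for tag in op.genes:
            labels[tag] = i
    return labels


def write_operons(operons: Sequence[Operon], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("operon_id\tstrand\tgenes\tn_genes\tprimary_tss\t"
                 "terminator\n")
        for op in operons:
            fh.write(f"{op.operon_id}\t{op.strand}\t{','.join(op.genes)}\t"
                     f"{len(op.genes)}\t{op.primary_tss or ''}\t"
                     f"{op.terminal_terminator or ''}\n")
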