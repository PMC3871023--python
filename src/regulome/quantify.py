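"""Sample pooling and NPKM expression quantification.

NPKM (nucleotide activity per kilobase per million mapped nucleotides) is
the per-base analogue of RPKM: for a region [n, m] on one strand,

    NPKM = 1e9 * sum_{i=n..m} f(i) / (G * len)

where f(i) is the strand-specific base activity, G is the genome-wide
total activity over both strands (library size in mapped nucleotides), and
``len`` is the region length - ``m - n + 1`` under the default inclusive
convention that matches published feature lengths, or the alternative
``m - n`` available as a switch.

Pooling follows the published noise rule: within each sample, every read
whose whole span has coverage exactly one and that neither overlaps nor is
bookended (end + 1 == next start) by another same-strand read is dropped
before the samples are combined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    CoverageTrack,
    GenomeAnnotation,
    MINUS,
    PLUS,
    ReadAlignment,
    StrandedInterval,
    coverage_from_reads,
    sense_overlap,
)

LENGTH_CONVENTIONS = ("inclusive", "printed")


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def singleton_filter(reads: Sequence[ReadAlignment]) -> list[ReadAlignment]:
    """Drop isolated single-coverage reads from one sample.

    A read survives iff some other read on the same strand overlaps it or
    is directly adjacent (bookended) to it.  Idempotent: the survivors of
    one pass all keep their witnesses, so a second pass changes nothing.
    """
    kept: list[ReadAlignment] = []
    by_strand: dict[str, list[ReadAlignment]] = {PLUS: [], MINUS: []}
    for r in reads:
        by_strand[r.interval.strand].append(r)
    for strand_reads in by_strand.values():
        strand_reads.sort(key=lambda r: (r.interval.start, r.interval.end))
        n = len(strand_reads)
        ends = np.array([r.interval.end for r in strand_reads], dtype=np.int64)
        starts = np.array([r.interval.start for r in strand_reads],
                          dtype=np.int64)
        prefix_max_end = np.maximum.accumulate(ends)
        for i, r in enumerate(strand_reads):
            left_contact = i > 0 and prefix_max_end[i - 1] >= starts[i] - 1
            right_contact = i < n - 1 and starts[i + 1] <= ends[i] + 1
            if left_contact or right_contact:
                kept.append(r)
    kept.sort(key=lambda r: (r.interval.strand, r.interval.start,
                             r.interval.end))
    return kept


def pool_samples(reads_per_sample: Mapping[str, Sequence[ReadAlignment]],
                 genome_length: int, circular: bool = False) -> CoverageTrack:
    """Singleton-filter each sample, then sum coverage across samples."""
    pooled = CoverageTrack(genome_length)
    for sid in sorted(reads_per_sample):
        track = coverage_from_reads(singleton_filter(reads_per_sample[sid]),
                                    genome_length, circular)
        pooled.fwd += track.fwd
        pooled.rev += track.rev
    return pooled


def mask_structural_reads(reads: Sequence[ReadAlignment],
                          annotation: GenomeAnnotation
                          ) -> list[ReadAlignment]:
    """Drop reads overlapping rRNA/tRNA genes on the same strand (the
    depletion step applied before library sizes are computed)."""
    structural = [g.interval for g in annotation.structural_rnas()]
    return [r for r in reads
            if not any(sense_overlap(r.interval, iv) for iv in structural)]


# ---------------------------------------------------------------------------
# NPKM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NpkmContext:
    """Inputs of one NPKM evaluation (region, strand activity, library size)."""

    n: int
    m: int
    strand: str
    f: np.ndarray  # strand-specific base activity over [n, m]
    G: int  # genome-wide total activity, both strands
    length_convention: str = "inclusive"

    def __post_init__(self) -> None:
        if self.n > self.m:
            raise ValueError(f"n > m ({self.n} > {self.m})")
        if self.length_convention not in LENGTH_CONVENTIONS:
            raise ValueError(
                f"unknown length convention {self.length_convention!r}")
        if len(self.f) != self.m - self.n + 1:
            raise ValueError("f must cover exactly [n, m]")


def npkm(ctx: NpkmContext) -> float:
    """Evaluate the NPKM of one region; raises on an empty dataset (G=0)."""
    if ctx.G <= 0:
        raise ValueError("empty dataset: total activity G must be positive")
    if ctx.length_convention == "inclusive":
        length = ctx.m - ctx.n + 1
    else:  # the alternative printed-formula convention
        length = ctx.m - ctx.n
        if length == 0:
            raise ValueError("printed convention undefined for n == m")
    return 1e9 * float(ctx.f.sum()) / (ctx.G * length)


def npkm_region(track: CoverageTrack, strand: str, n: int, m: int,
                G: int | None = None,
                length_convention: str = "inclusive") -> float:
    """NPKM of [n, m] on one strand of a coverage track."""
    if G is None:
        G = track.total_activity()
    ctx = NpkmContext(n, m, strand, track.activity(strand)[n - 1:m], G,
                      length_convention)
    return npkm(ctx)


def npkm_interval(track: CoverageTrack, iv: StrandedInterval,
                  G: int | None = None,
                  length_convention: str = "inclusive") -> float:
    return npkm_region(track, iv.strand, iv.start, iv.end, G,
                       length_convention)


def npkm_matrix(features: Iterable[object],
                tracks: Mapping[str, CoverageTrack],
                length_convention: str = "inclusive") -> pd.DataFrame:
    """Feature x sample NPKM table; each sample is normalized by its own G.

    ``features`` may be any objects carrying an ``interval`` plus a
    ``feature_id`` or ``locus_tag`` identifier (RNA features, gene records,
    planted truth features).
    """
    feats = []
    for f in features:
        fid = getattr(f, "feature_id", None) or getattr(f, "locus_tag")
        feats.append((fid, f.interval))
    sample_ids = sorted(tracks)
    totals = {sid: tracks[sid].total_activity() for sid in sample_ids}
    data = np.zeros((len(feats), len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        track = tracks[sid]
        for i, (fid, iv) in enumerate(feats):
            data[i, j] = npkm_interval(track, iv, totals[sid],
                                       length_convention)
    return pd.DataFrame(data, index=[fid for fid, _ in feats],
                        columns=sample_ids)
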