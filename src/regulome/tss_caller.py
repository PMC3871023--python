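"""Transcription start site calling from dRNA-Seq coverage tracks.

A candidate TSS is a base whose log coverage step over its upstream
neighbor (in transcription direction) exceeds ln 4.  Candidates in the
promoter regions of structural RNAs are masked, nearby candidates are
merged keeping the strongest, sites are matched across sampling points,
and every retained site is classified:

* ``P`` - within 500 bp upstream of a same-strand annotated start codon
* ``I`` - inside a same-strand gene
* ``A`` - inside an opposite-strand gene
* ``O`` - orphan: none of the above

A site may carry several of P/I/A; O is exclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_model import (
    CoverageTrack,
    GenomeAnnotation,
    MINUS,
    PLUS,
    SAMPLING_POINTS,
    StrandedInterval,
    write_bed,
)

TSS_CLASSES = ("P", "I", "A", "O")


@dataclass(frozen=True)
class TssRecord:
    position: int  # 1-based
    strand: str
    step: float  # natural-log coverage increase
    supporting_points: tuple[str, ...] = ()
    supported: bool = False
    classes: tuple[str, ...] = ()
    linked_feature: str | None = None


def detect_tss(track: CoverageTrack, strand: str, min_ratio: float = 4.0,
               pseudocount: float = 1.0) -> list[TssRecord]:
    """Scan one strand of a dRNA-Seq track for log-step candidates.

    Base p is a candidate iff ``ln((cov(p)+c) / (cov(up)+c)) > ln(min_ratio)``
    where ``up`` is the upstream neighbor in transcription direction (p-1
    on '+', p+1 on '-') and ``c`` is a pseudocount guarding zero coverage.
    """
    cov = track.activity(strand).astype(float)
    if strand == PLUS:
        upstream = np.concatenate(([0.0], cov[:-1]))
    else:
        upstream = np.concatenate((cov[1:], [0.0]))
    steps = np.log((cov + pseudocount) / (upstream + pseudocount))
    hits = np.flatnonzero(steps > math.log(min_ratio))
    return [TssRecord(int(i) + 1, strand, float(steps[i])) for i in hits]


def filter_structural(tss: Sequence[TssRecord], annotation: GenomeAnnotation,
                      window: int = 500) -> list[TssRecord]:
    """Drop candidates in promoter regions of, or inside, rRNA/tRNA genes."""
    out = []
    structural = annotation.structural_rnas()
    for t in tss:
        masked = False
        for g in structural:
            if g.strand != t.strand:
                continue
            iv = g.interval
            if iv.contains(t.position):
                masked = True
                break
            if t.strand == PLUS and iv.start - window <= t.position < iv.start:
                masked = True
                break
            if t.strand == MINUS and iv.end < t.position <= iv.end + window:
                masked = True
                break
        if not masked:
            out.append(t)
    return out


def _chains(records: Sequence[TssRecord], window: int
            ) -> Iterable[list[TssRecord]]:
    """Maximal same-strand runs of candidates pairwise closer than window."""
    for strand in (PLUS, MINUS):
        group = sorted((t for t in records if t.strand == strand),
                       key=lambda t: t.position)
        chain: list[TssRecord] = []
        for t in group:
            if chain and t.position - chain[-1].position < window:
                chain.append(t)
            else:
                if chain:
                    yield chain
                chain = [t]
        if chain:
            yield chain


def _strongest(chain: Sequence[TssRecord]) -> TssRecord:
    """Largest step wins; ties break toward the smaller coordinate."""
    return max(chain, key=lambda t: (t.step, -t.position))


def merge_nearby(tss: Sequence[TssRecord], window: int = 20,
                 drop_all: bool = False) -> list[TssRecord]:
    """Resolve candidates closer than ``window`` on the same strand.

    By default the strongest member of each chain survives (5'-end
    micro-heterogeneity collapses onto the dominant position); with
    ``drop_all`` every member of a multi-candidate chain is discarded.
    """
    out = []
    for chain in _chains(tss, window):
        if len(chain) == 1:
            out.append(chain[0])
        elif not drop_all:
            out.append(_strongest(chain))
    out.sort(key=lambda t: (t.position, t.strand))
    return out


def cross_sample_support(tss_per_point: Mapping[str, Sequence[TssRecord]],
                         window: int = 20, min_support: int = 2
                         ) -> list[TssRecord]:
    """Match per-sampling-point candidates into consensus sites.

    Candidates from different points within ``window`` on the same strand
    are one site; the consensus position comes from the point with the
    largest step.  Sites seen in at least ``min_support`` points are marked
    supported (all sites are retained).
    """
    tagged: list[tuple[TssRecord, str]] = []
    for point, records in tss_per_point.items():
        tagged.extend((t, point) for t in records)
    # reuse the chain machinery on the flattened candidate list
    flat = [replace(t, supporting_points=(point,))
            for t, point in tagged]
    out = []
    for chain in _chains(flat, window):
        points = sorted({p for t in chain for p in t.supporting_points},
                        key=SAMPLING_POINTS.index)
        best = _strongest(chain)
        out.append(replace(best, supporting_points=tuple(points),
                           supported=len(points) >= min_support))
    out.sort(key=lambda t: (t.position, t.strand))
    return out


def classify_tss(tss: Sequence[TssRecord], annotation: GenomeAnnotation,
                 utr_window: int = 500) -> list[TssRecord]:
    """Assign every applicable class of P/I/A; O iff none applies."""
    out = []
    for t in tss:
        classes: set[str] = set()
        for g in annotation.genes:
            iv = g.interval
            if iv.contains(t.position):
                classes.add("I" if g.strand == t.strand else "A")
            if g.strand == t.strand:
                if (t.strand == PLUS
                        and iv.start - utr_window <= t.position < iv.start):
                    classes.add("P")
                if (t.strand == MINUS
                        and iv.end < t.position <= iv.end + utr_window):
                    classes.add("P")
        out.append(replace(t, classes=tuple(sorted(classes)) or ("O",)))
    return out


def call_tss(drna_tracks: Mapping[str, CoverageTrack],
             annotation: GenomeAnnotation, min_ratio: float = 4.0,
             pseudocount: float = 1.0, structural_window: int = 500,
             merge_window: int = 20, min_support: int = 2,
             promoter_window: int = 500, drop_all: bool = False
             ) -> list[TssRecord]:
    """Full per-point detect -> filter -> merge, then cross-point consensus
    and classification."""
    per_point: dict[str, list[TssRecord]] = {}
    for point in sorted(drna_tracks):
        track = drna_tracks[point]
        cands = (detect_tss(track, PLUS, min_ratio, pseudocount)
                 + detect_tss(track, MINUS, min_ratio, pseudocount))
        cands = filter_structural(cands, annotation, structural_window)
        per_point[point] = merge_nearby(cands, merge_window, drop_all)
    consensus = cross_sample_support(per_point, merge_window, min_support)
    return classify_tss(consensus, annotation, promoter_window)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_tss_bed(tss: Sequence[TssRecord], path: str | Path,
                  chrom: str = "chr") -> None:
    """BED6: one base per record, name = classes joined by '|',
    score = step in milli-nats."""
    rows = [(StrandedInterval(chrom, t.position, t.position, t.strand),
             "|".join(t.classes) or ".", int(round(t.step * 1000)))
            for t in tss]
    write_bed(rows, path)


def write_tss_tsv(tss: Sequence[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tstrand\tstep\tclasses\tsupporting_points\t"
                 "supported\n")
        for t in tss:
            fh.write(f"{t.position}\t{t.strand}\t{t.step:.4f}\t"
                     f"{'|'.join(t.classes)}\t"
                     f"{','.join(t.supporting_points)}\t"
                     f"{int(t.supported)}\n")


def read_tss_tsv(path: str | Path) -> list[TssRecord]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            pos, strand, step, classes, points, supp = \
                line.rstrip("\n").split("\t")
            out.append(TssRecord(
                int(pos), strand, float(step),
                tuple(p for p in points.split(",") if p),
                bool(int(supp)),
                tuple(c for c in classes.split("|") if c)))
    return out
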