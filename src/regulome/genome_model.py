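"""Coordinate, annotation and coverage primitives shared by every pipeline stage.

Conventions
-----------
* Genomic coordinates are 1-based and inclusive on both ends, with an
  explicit strand and ``start <= end`` always.  Publication-style tables
  for minus-strand features print the pair reversed (start > stop); that
  notation is applied only at the I/O boundary (:meth:`StrandedInterval.
  to_printed` / :meth:`StrandedInterval.from_printed`).
* bedGraph files use the format's native 0-based half-open intervals; the
  conversion lives entirely in :func:`read_coverage` / :func:`write_coverage`.
* Coverage is held per strand as a dense integer vector of per-base
  activity f(i) (number of reads covering base i); the combined activity
  g(i) sums both strands and backs library-size normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger("regulome")

PLUS = "+"
MINUS = "-"
STRANDS = (PLUS, MINUS)

#: gene kinds retained from an annotation
GENE_KINDS = ("CDS", "rRNA", "tRNA", "pseudo")

#: structural RNA kinds whose promoters are masked during TSS calling
STRUCTURAL_RNA_KINDS = ("rRNA", "tRNA")


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class StrandedInterval:
    """A stranded genomic interval, 1-based inclusive, ``start <= end``."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end < start ({self.end} < {self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_printed(cls, chrom: str, start: int, stop: int,
                     strand: str | None = None) -> "StrandedInterval":
        """Build from publication notation where start > stop encodes '-'."""
        if start <= stop:
            return cls(chrom, start, stop, strand or PLUS)
        return cls(chrom, stop, start, strand or MINUS)

    def to_printed(self) -> tuple[int, int]:
        """(start, stop) pair in publication notation (reversed on '-')."""
        if self.strand == MINUS:
            return self.end, self.start
        return self.start, self.end

    @property
    def five_prime(self) -> int:
        """Coordinate of the 5' end in transcription direction."""
        return self.end if self.strand == MINUS else self.start

    @property
    def three_prime(self) -> int:
        """Coordinate of the 3' end in transcription direction."""
        return self.start if self.strand == MINUS else self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def contains_interval(self, other: "StrandedInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.start and other.end <= self.end)


def interval_length(iv: StrandedInterval) -> int:
    """Number of bases spanned by ``iv`` (end − start + 1)."""
    return iv.length


def span_overlap(a: StrandedInterval, b: StrandedInterval) -> int:
    """Shared bases of the two spans, ignoring strand; 0 across chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def antisense_overlap(a: StrandedInterval, b: StrandedInterval) -> int:
    """Shared bases between opposite-strand intervals; 0 if strands match."""
    if a.strand == b.strand:
        return 0
    return span_overlap(a, b)


def sense_overlap(a: StrandedInterval, b: StrandedInterval) -> int:
    """Shared bases between same-strand intervals; 0 if strands differ."""
    if a.strand != b.strand:
        return 0
    return span_overlap(a, b)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    locus_tag: str
    kind: str  # one of GENE_KINDS
    interval: StrandedInterval
    name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in GENE_KINDS:
            raise ValueError(f"unknown gene kind {self.kind!r}")

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class Terminator:
    term_id: str
    interval: StrandedInterval


@dataclass
class GenomeAnnotation:
    """A genome's gene and terminator annotation."""

    genome_length: int
    circular: bool = True
    chrom: str = "chr"
    genes: list[GeneRecord] = field(default_factory=list)
    terminators: list[Terminator] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.locus_tag in seen:
                raise ValueError(f"duplicate locus_tag {g.locus_tag!r}")
            seen.add(g.locus_tag)
            if g.interval.end > self.genome_length:
                raise ValueError(
                    f"gene {g.locus_tag} exceeds genome length "
                    f"{self.genome_length}")
        for t in self.terminators:
            if t.interval.end > self.genome_length:
                raise ValueError(
                    f"terminator {t.term_id} exceeds genome length")
        self.genes.sort(key=lambda g: (g.interval.start, g.interval.end))

    def genes_on(self, strand: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.strand == strand]

    def gene(self, locus_tag: str) -> GeneRecord:
        for g in self.genes:
            if g.locus_tag == locus_tag:
                return g
        raise KeyError(locus_tag)

    def structural_rnas(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.kind in STRUCTURAL_RNA_KINDS]


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Dense per-base, per-strand activity over a genome of length L.

    ``fwd[i-1]`` / ``rev[i-1]`` hold the base activity f(i) of base i on the
    plus / minus strand.
    """

    genome_length: int
    fwd: np.ndarray = None  # type: ignore[assignment]
    rev: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fwd is None:
            self.fwd = np.zeros(self.genome_length, dtype=np.int64)
        if self.rev is None:
            self.rev = np.zeros(self.genome_length, dtype=np.int64)
        for arr in (self.fwd, self.rev):
            if len(arr) != self.genome_length:
                raise ValueError("strand vector length != genome length")
            if (arr < 0).any():
                raise ValueError("negative coverage")

    def activity(self, strand: str) -> np.ndarray:
        return self.fwd if strand == PLUS else self.rev

    def combined(self) -> np.ndarray:
        """g(i) = f_plus(i) + f_minus(i)."""
        return self.fwd + self.rev

    def total_activity(self) -> int:
        """Genome-wide total of g(i) over both strands."""
        return int(self.fwd.sum() + self.rev.sum())

    def region_sum(self, strand: str, start: int, end: int) -> int:
        """Sum of f(i) over bases start..end (1-based inclusive)."""
        return int(self.activity(strand)[start - 1:end].sum())

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(self.genome_length, self.fwd.copy(),
                             self.rev.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return (self.genome_length == other.genome_length
                and np.array_equal(self.fwd, other.fwd)
                and np.array_equal(self.rev, other.rev))


@dataclass(frozen=True)
class ReadAlignment:
    """A mapped sequencing read reduced to its stranded genomic span."""

    interval: StrandedInterval
    sample_id: str = ""


def coverage_from_reads(reads: Iterable[ReadAlignment], genome_length: int,
                        circular: bool = False) -> CoverageTrack:
    """Accumulate per-base coverage from read alignments.

    Reads whose span runs past the genome end wrap around the origin when
    ``circular`` is true and raise otherwise.
    """
    track = CoverageTrack(genome_length)
    for read in reads:
        iv = read.interval
        arr = track.activity(iv.strand)
        if iv.end <= genome_length:
            arr[iv.start - 1:iv.end] += 1
        elif circular:
            arr[iv.start - 1:genome_length] += 1
            arr[0:iv.end - genome_length] += 1
        else:
            raise ValueError(
                f"read {iv} outside linear genome of length {genome_length}")
    return track


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

SAMPLING_POINTS = ("I", "II", "III", "IV", "V")
REPLICATES = ("L", "R", "M")
ASSAYS = ("rnaseq", "drnaseq")


@dataclass(frozen=True)
class SampleInfo:
    sampling_point: str
    replicate: str
    assay: str

    def __post_init__(self) -> None:
        if self.sampling_point not in SAMPLING_POINTS:
            raise ValueError(f"unknown sampling point {self.sampling_point!r}")
        if self.replicate not in REPLICATES:
            raise ValueError(f"unknown replicate {self.replicate!r}")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")


@dataclass
class SampleSheet:
    samples: dict[str, SampleInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        triples = [(s.sampling_point, s.replicate, s.assay)
                   for s in self.samples.values()]
        if len(triples) != len(set(triples)):
            raise ValueError("duplicate (point, replicate, assay) triple")

    def ids_for(self, sampling_point: str | None = None,
                assay: str | None = None) -> list[str]:
        out = []
        for sid, info in self.samples.items():
            if sampling_point and info.sampling_point != sampling_point:
                continue
            if assay and info.assay != assay:
                continue
            out.append(sid)
        return sorted(out)

    def __iter__(self) -> Iterator[tuple[str, SampleInfo]]:
        return iter(sorted(self.samples.items()))


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

_GFF_KIND_MAP = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA",
                 "pseudogene": "pseudo"}
_KIND_GFF_MAP = {v: k for k, v in _GFF_KIND_MAP.items()}


def read_annotation(path: str | Path, circular: bool = True) -> GenomeAnnotation:
    """Load genes and terminators from a GFF3 file.

    Feature types CDS/rRNA/tRNA/pseudogene become :class:`GeneRecord`;
    type ``terminator`` becomes :class:`Terminator`; anything else is
    skipped with a warning.  The genome length comes from the
    ``##sequence-region`` pragma.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    genome_length = None
    chrom = "chr"
    try:
        db = gffutils.create_db(str(path), dbfn=":memory:", keep_order=True,
                                merge_strategy="create_unique")
    except EmptyInputError:
        # pragma-only file: a valid annotation with zero features
        directives = [line[2:].strip() for line in
                      Path(path).read_text().splitlines()
                      if line.startswith("##")]
        for directive in directives:
            if directive.startswith("sequence-region"):
                parts = directive.split()
                chrom, genome_length = parts[1], int(parts[3])
        if genome_length is None:
            raise ValueError(f"{path}: missing ##sequence-region pragma")
        return GenomeAnnotation(genome_length, circular, chrom, [], [])
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            chrom = parts[1]
            genome_length = int(parts[3])
    if genome_length is None:
        raise ValueError(f"{path}: missing ##sequence-region pragma")

    genes: list[GeneRecord] = []
    terminators: list[Terminator] = []
    for feat in db.all_features():
        iv = StrandedInterval(feat.seqid, feat.start, feat.end, feat.strand)
        if feat.featuretype in _GFF_KIND_MAP:
            locus = feat.attributes.get("locus_tag",
                                        feat.attributes.get("ID", [feat.id]))[0]
            name = feat.attributes.get("Name", [None])[0]
            genes.append(GeneRecord(locus, _GFF_KIND_MAP[feat.featuretype],
                                    iv, name))
        elif feat.featuretype == "terminator":
            tid = feat.attributes.get("ID", [feat.id])[0]
            terminators.append(Terminator(tid, iv))
        else:
            logger.warning("skipping unknown feature type %r at %s:%d-%d",
                           feat.featuretype, feat.seqid, feat.start, feat.end)
    return GenomeAnnotation(genome_length, circular, chrom, genes, terminators)


def write_annotation(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write an annotation back to GFF3 (round-trips with read_annotation)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {ann.chrom} 1 {ann.genome_length}\n")
        rows = []
        for g in ann.genes:
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
            if g.name:
                attrs += f";Name={g.name}"
            rows.append((g.interval.start, g.interval.end,
                         _KIND_GFF_MAP[g.kind], g.interval.strand, attrs))
        for t in ann.terminators:
            rows.append((t.interval.start, t.interval.end, "terminator",
                         t.interval.strand, f"ID={t.term_id}"))
        for start, end, ftype, strand, attrs in sorted(rows):
            fh.write(f"{ann.chrom}\tregulome\t{ftype}\t{start}\t{end}\t.\t"
                     f"{strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# bedGraph coverage I/O
# ---------------------------------------------------------------------------

def write_coverage(track: CoverageTrack, path_plus: str | Path,
                   path_minus: str | Path, chrom: str = "chr") -> None:
    """Write one bedGraph per strand (0-based half-open, zero runs omitted)."""
    for strand, path in ((PLUS, path_plus), (MINUS, path_minus)):
        arr = track.activity(strand)
        with open(path, "w") as fh:
            for start0, end0, value in _runs(arr):
                if value:
                    fh.write(f"{chrom}\t{start0}\t{end0}\t{value}\n")


def _runs(arr: np.ndarray) -> Iterator[tuple[int, int, int]]:
    """Yield maximal (start0, end0, value) runs of equal values."""
    if len(arr) == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(arr)]))
    for s, e in zip(starts, ends):
        yield int(s), int(e), int(arr[s])


def read_coverage(path_plus: str | Path, path_minus: str | Path,
                  genome_length: int) -> CoverageTrack:
    """Read a per-strand bedGraph pair written by :func:`write_coverage`."""
    track = CoverageTrack(genome_length)
    for strand, path in ((PLUS, path_plus), (MINUS, path_minus)):
        arr = track.activity(strand)
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                _, start0, end0, value = line.split()
                arr[int(start0):int(end0)] = int(float(value))
    return track


# ---------------------------------------------------------------------------
# BED6 I/O (read intervals, TSS output)
# ---------------------------------------------------------------------------

def write_bed(intervals: Sequence[tuple[StrandedInterval, str, int]],
              path: str | Path) -> None:
    """Write BED6 rows from (interval, name, score) triples."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t"
                     f"{score}\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[tuple[StrandedInterval, str, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            score = int(float(fields[4])) if len(fields) > 4 else 0
            strand = fields[5] if len(fields) > 5 else PLUS
            out.append((StrandedInterval(chrom, start0 + 1, end0, strand),
                        name, score))
    return out


def write_reads(reads: Sequence[ReadAlignment], path: str | Path) -> None:
    write_bed([(r.interval, r.sample_id or ".", 0) for r in reads], path)


def read_reads(path: str | Path) -> list[ReadAlignment]:
    return [ReadAlignment(iv, name if name != "." else "")
            for iv, name, _ in read_bed(path)]


# ---------------------------------------------------------------------------
# TSV I/O: terminators, sample sheet
# ---------------------------------------------------------------------------

def write_terminators(terminators: Sequence[Terminator], path: str | Path,
                      chrom: str = "chr") -> None:
    with open(path, "w") as fh:
        fh.write("seq\tstart\tend\tstrand\tid\n")
        for t in terminators:
            iv = t.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                     f"{t.term_id}\n")


def read_terminators(path: str | Path) -> list[Terminator]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            seq, start, end, strand, tid = line.rstrip("\n").split("\t")
            out.append(Terminator(
                tid, StrandedInterval(seq, int(start), int(end), strand)))
    return out


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpoint\treplicate\tassay\n")
        for sid, info in sheet:
            fh.write(f"{sid}\t{info.sampling_point}\t{info.replicate}\t"
                     f"{info.assay}\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    samples = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            sid, point, rep, assay = line.rstrip("\n").split("\t")
            samples[sid] = SampleInfo(point, rep, assay)
    return SampleSheet(samples)
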