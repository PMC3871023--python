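"""Synthetic genome, RNA-Seq and dRNA-Seq generator with planted ground truth.

The generator emulates the study design the pipeline targets: a circular
bacterial chromosome carrying protein/rRNA/tRNA genes grouped into operons,
each transcribed from a planted transcription start site (TSS) 20-300 nt
upstream of its first gene through a 3'UTR ending at an intrinsic
terminator.  Some terminators are leaky: transcription reads through at a
configurable fraction with geometric per-base decay.  Expression follows a
5-sampling-point x 3-replicate design; replicate variation is Poisson.

Every one of the ten RNA feature classes is planted at least once:

====== =====================================================================
class  planted construct
====== =====================================================================
5'UTR  region between each operon TSS and its first start codon
3'UTR  region between each operon's last stop codon and the transcript end
A_5'UTR a 5'UTR overlapping an opposite-strand gene by more than 100 nt
A_3'UTR a leaky-terminator 3'UTR protruding over an opposite gene (>100 nt)
A_rt   intergenic read-through between two same-strand transcripts, past
       the upstream terminator and antisense to an opposite gene
A_I    ncRNA wholly antisense within a single gene body
A_5    ncRNA wholly antisense within a 5'UTR
A_3    ncRNA wholly antisense within a 3'UTR
A_misc ncRNA antisense across two genes
indep  intergenic ncRNA with no antisense partner
====== =====================================================================

Reads are simulated as stranded 50-nt intervals (no nucleotide content;
random FASTA is available separately for format validity and the ORF
screen).  Each transcript is tiled in adjacent 50-nt windows, so noise-free
coverage is exactly the programmed depth at every transcribed base and the
planted feature boundaries are recovered exactly by the downstream caller.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genome_model import (
    CoverageTrack,
    GeneRecord,
    GenomeAnnotation,
    MINUS,
    PLUS,
    ReadAlignment,
    SAMPLING_POINTS,
    REPLICATES,
    SampleInfo,
    SampleSheet,
    StrandedInterval,
    Terminator,
    coverage_from_reads,
)

RNA_CLASSES = ("5'UTR", "3'UTR", "A_5'UTR", "A_3'UTR", "A_rt",
               "A_5", "A_3", "A_I", "A_misc", "indep")

#: expression archetypes over sampling points I..V (relative depth factors)
PROFILE_ARCHETYPES: dict[str, tuple[float, ...]] = {
    "up_late": (0.2, 0.3, 0.5, 2.0, 3.0),
    "down": (3.0, 2.0, 0.5, 0.3, 0.2),
    "peak_mid": (0.3, 2.0, 3.0, 2.0, 0.3),
    "valley_mid": (2.5, 0.5, 0.2, 0.5, 2.5),
}
#: used once so that at least one TSS is silent at early sampling points
PROFILE_OFF_EARLY = (0.0, 0.0, 1.0, 2.0, 2.0)

_DEPTH_CHOICES = (10, 20, 40, 80)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; the seed fully determines all outputs."""

    genome_length: int = 150_000
    gene_count: int = 48
    read_length: int = 50
    #: operon size -> probability (sizes of ordinary filler operons)
    operon_size_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.65, 2: 0.20, 3: 0.10, 4: 0.05})
    #: per-sampling-point global depth multipliers (I..V)
    point_multipliers: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    poisson_noise: bool = True
    #: fraction of polymerases reading through a leaky terminator
    readthrough_fraction: float = 0.1
    #: per-base geometric decay rate of read-through coverage
    readthrough_decay: float = 0.0
    #: dRNA-Seq coverage step factor at a native 5' end
    drnaseq_enrichment: int = 20
    #: dRNA-Seq processed-end background (expected coverage per base)
    drnaseq_background: float = 0.0
    #: expected isolated background reads per RNA-Seq sample
    background_reads_per_sample: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.read_length != 50:
            raise ValueError("the tiling scheme is built around 50 nt reads")
        if abs(sum(self.operon_size_probs.values()) - 1.0) > 1e-9:
            raise ValueError("operon size probabilities must sum to 1")

    @classmethod
    def noise_free(cls, **kw) -> "SimulationConfig":
        """Deterministic coverage: programmed depths, no sampling noise."""
        kw.setdefault("poisson_noise", False)
        kw.setdefault("background_reads_per_sample", 0.0)
        kw.setdefault("drnaseq_background", 0.0)
        return cls(**kw)

    def rngs(self) -> tuple[np.random.Generator, ...]:
        """(genome, rnaseq, drnaseq) streams derived from the one seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(c) for c in children)


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedTss:
    position: int
    strand: str
    classes: tuple[str, ...]
    active_points: tuple[str, ...]
    unit_id: str


@dataclass(frozen=True)
class PlantedFeature:
    feature_id: str
    interval: StrandedInterval
    rna_class: str
    parent_gene: str | None = None


@dataclass(frozen=True)
class PlantedOperon:
    operon_id: str
    strand: str
    genes: tuple[str, ...]


@dataclass(frozen=True)
class TranscriptionUnit:
    """A planted transcript: core span plus optional terminator read-through."""

    unit_id: str
    interval: StrandedInterval  # core transcript span (TSS..terminator end)
    base_depth: float
    profile: tuple[float, ...]
    rt_windows: int = 0  # 50-nt read-through windows past the 3' end

    @property
    def strand(self) -> str:
        return self.interval.strand

    def point_mean(self, point_idx: int, config: SimulationConfig) -> float:
        return (self.base_depth * self.profile[point_idx]
                * config.point_multipliers[point_idx])

    def active_points(self, config: SimulationConfig) -> tuple[str, ...]:
        return tuple(p for i, p in enumerate(SAMPLING_POINTS)
                     if _round_half_up(self.point_mean(i, config)) >= 1)

    def windows(self, config: SimulationConfig) -> list[tuple[StrandedInterval, bool, int]]:
        """(window, is_readthrough, rt_index) tiles in transcription order."""
        iv = self.interval
        n_core = iv.length // config.read_length
        if iv.length % config.read_length:
            raise ValueError(f"{self.unit_id}: span not a read-length multiple")
        out = []
        w = config.read_length
        for j in range(n_core + self.rt_windows):
            rt = j >= n_core
            if iv.strand == PLUS:
                lo = iv.start + j * w
            else:
                lo = iv.end - (j + 1) * w + 1
            out.append((StrandedInterval(iv.chrom, lo, lo + w - 1, iv.strand),
                        rt, j - n_core + 1 if rt else 0))
        return out

    def rt_depth(self, mean: float, rt_index: int,
                 config: SimulationConfig) -> float:
        decay = (1.0 - config.readthrough_decay) ** (config.read_length * rt_index)
        return mean * config.readthrough_fraction * decay


@dataclass
class TruthTable:
    planted_tss: list[PlantedTss] = field(default_factory=list)
    planted_features: list[PlantedFeature] = field(default_factory=list)
    planted_operons: list[PlantedOperon] = field(default_factory=list)
    expression_program: dict[str, tuple[float, ...]] = field(default_factory=dict)
    leaky_terminators: dict[str, float] = field(default_factory=dict)
    transcription_units: list[TranscriptionUnit] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in RNA_CLASSES}
        for f in self.planted_features:
            counts[f.rna_class] += 1
        return counts

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        def iv(i: StrandedInterval) -> dict:
            return {"chrom": i.chrom, "start": i.start, "end": i.end,
                    "strand": i.strand}

        payload = {
            "planted_tss": [
                {"position": t.position, "strand": t.strand,
                 "classes": list(t.classes),
                 "active_points": list(t.active_points),
                 "unit_id": t.unit_id}
                for t in self.planted_tss],
            "planted_features": [
                {"feature_id": f.feature_id, "interval": iv(f.interval),
                 "rna_class": f.rna_class, "parent_gene": f.parent_gene}
                for f in self.planted_features],
            "planted_operons": [
                {"operon_id": o.operon_id, "strand": o.strand,
                 "genes": list(o.genes)}
                for o in self.planted_operons],
            "expression_program": {k: list(v) for k, v
                                   in self.expression_program.items()},
            "leaky_terminators": dict(self.leaky_terminators),
            "transcription_units": [
                {"unit_id": u.unit_id, "interval": iv(u.interval),
                 "base_depth": u.base_depth, "profile": list(u.profile),
                 "rt_windows": u.rt_windows}
                for u in self.transcription_units],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        d = json.loads(Path(path).read_text())

        def iv(j: dict) -> StrandedInterval:
            return StrandedInterval(j["chrom"], j["start"], j["end"],
                                    j["strand"])

        return cls(
            planted_tss=[PlantedTss(t["position"], t["strand"],
                                    tuple(t["classes"]),
                                    tuple(t["active_points"]), t["unit_id"])
                         for t in d["planted_tss"]],
            planted_features=[PlantedFeature(f["feature_id"],
                                             iv(f["interval"]),
                                             f["rna_class"], f["parent_gene"])
                              for f in d["planted_features"]],
            planted_operons=[PlantedOperon(o["operon_id"], o["strand"],
                                           tuple(o["genes"]))
                             for o in d["planted_operons"]],
            expression_program={k: tuple(v) for k, v
                                in d["expression_program"].items()},
            leaky_terminators=dict(d["leaky_terminators"]),
            transcription_units=[
                TranscriptionUnit(u["unit_id"], iv(u["interval"]),
                                  u["base_depth"], tuple(u["profile"]),
                                  u["rt_windows"])
                for u in d["transcription_units"]],
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

class _Assembler:
    """Places constructs left to right and accumulates annotation + truth."""

    #: genes consumed by the obligatory special constructs
    SPECIAL_GENES = 16
    #: unexpressed structural / pseudo genes
    STRUCTURAL_GENES = 4

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.chrom = "chr"
        self.cursor = 1 + 300  # clearance after the origin (circular genome)
        self.genes: list[GeneRecord] = []
        self.terminators: list[Terminator] = []
        self.truth = TruthTable()
        self._n_gene = 0
        self._n_unit = 0
        self._n_term = 0
        self._n_feat = 0
        self._n_operon = 0

    # -- id factories -------------------------------------------------------

    def _gene_id(self) -> str:
        self._n_gene += 1
        return f"g{self._n_gene:04d}"

    def _unit_id(self) -> str:
        self._n_unit += 1
        return f"u{self._n_unit:04d}"

    def _term_id(self) -> str:
        self._n_term += 1
        return f"t{self._n_term:04d}"

    def _feat_id(self) -> str:
        self._n_feat += 1
        return f"nc{self._n_feat:04d}"

    def _operon_id(self) -> str:
        self._n_operon += 1
        return f"op{self._n_operon:04d}"

    # -- helpers ------------------------------------------------------------

    def _advance(self, footprint: int) -> int:
        """Reserve `footprint` bases; return the left genome coordinate."""
        left = self.cursor
        self.cursor += footprint
        gap = int(self.rng.integers(150, 401))
        self.cursor += gap
        if self.cursor > self.cfg.genome_length - 300:
            raise ValueError(
                "infeasible packing: genome_length "
                f"{self.cfg.genome_length} too small for the requested "
                "content (increase genome_length or reduce gene_count)")
        return left

    def _map(self, left: int, footprint: int, strand: str,
             t_lo: int, t_hi: int) -> StrandedInterval:
        """Map transcription-order offsets [t_lo, t_hi] to genome coords."""
        if strand == PLUS:
            return StrandedInterval(self.chrom, left + t_lo, left + t_hi,
                                    strand)
        return StrandedInterval(self.chrom, left + footprint - 1 - t_hi,
                                left + footprint - 1 - t_lo, strand)

    def _map_opp(self, left: int, footprint: int, host_strand: str,
                 t_lo: int, t_hi: int) -> StrandedInterval:
        """Map offsets in the host's transcription frame, then flip strand."""
        iv = self._map(left, footprint, host_strand, t_lo, t_hi)
        opp = MINUS if host_strand == PLUS else PLUS
        return StrandedInterval(iv.chrom, iv.start, iv.end, opp)

    def _profile(self) -> tuple[float, ...]:
        name = str(self.rng.choice(sorted(PROFILE_ARCHETYPES)))
        return PROFILE_ARCHETYPES[name]

    def _depth(self) -> float:
        return float(self.rng.choice(_DEPTH_CHOICES))

    # -- constructs ---------------------------------------------------------

    def operon(self, strand: str, n_genes: int, *,
               u5: int | None = None, min_u3: int = 30,
               rt_windows: int = 0,
               antisense_gene_in: str | None = None,
               profile: tuple[float, ...] | None = None,
               depth: float | None = None,
               opposite_ncrna_in: str | None = None) -> dict:
        """Plant one operon; optionally leaky, with an opposite gene or an
        opposite ncRNA inside one of its regions."""
        rng, cfg = self.rng, self.cfg
        depth = float(depth) if depth is not None else self._depth()
        profile = tuple(profile) if profile is not None else self._profile()
        u5 = int(u5 if u5 is not None else rng.integers(20, 301))
        lens = [int(rng.integers(400, 901)) for _ in range(n_genes)]
        gaps = [int(rng.integers(20, 81)) for _ in range(n_genes - 1)]
        genes_end = u5 + sum(lens) + sum(gaps)  # local, exclusive
        core = genes_end + min_u3
        core += (-core) % cfg.read_length  # pad 3'UTR to a window multiple
        u3 = core - genes_end
        rt_len = self._effective_rt(rt_windows, depth, profile) * cfg.read_length
        footprint = core + rt_len
        left = self._advance(footprint)

        # genes
        locus_ids = []
        pos = u5
        gene_locals = []
        for ln, gp in zip(lens, gaps + [0]):
            iv = self._map(left, footprint, strand, pos, pos + ln - 1)
            locus = self._gene_id()
            self.genes.append(GeneRecord(locus, "CDS", iv))
            locus_ids.append(locus)
            gene_locals.append((pos, pos + ln - 1))
            pos += ln + gp

        # terminator: last 30 bases of the core transcript
        term = Terminator(self._term_id(),
                          self._map(left, footprint, strand, core - 30,
                                    core - 1))
        self.terminators.append(term)
        if rt_windows:
            self.truth.leaky_terminators[term.term_id] = \
                cfg.readthrough_fraction

        # transcription unit
        unit = TranscriptionUnit(
            self._unit_id(), self._map(left, footprint, strand, 0, core - 1),
            depth, profile, rt_windows=rt_len // cfg.read_length)
        self.truth.transcription_units.append(unit)
        self.truth.expression_program[unit.unit_id] = tuple(
            unit.base_depth * f for f in unit.profile)

        # antisense partner gene (unexpressed) inside a chosen region
        if antisense_gene_in == "5utr":
            # fully inside the 5'UTR, overlap > 100 nt
            iv = self._map_opp(left, footprint, strand, 40, u5 - 40)
            self.genes.append(GeneRecord(self._gene_id(), "CDS", iv))
            self._singleton_operon(self.genes[-1])
        elif antisense_gene_in == "rt":
            iv = self._map_opp(left, footprint, strand, core + 20,
                               core + rt_len - 30)
            self.genes.append(GeneRecord(self._gene_id(), "CDS", iv))
            self._singleton_operon(self.genes[-1])

        # planted UTR features
        utr5_iv = self._map(left, footprint, strand, 0, u5 - 1)
        utr5_cls = "A_5'UTR" if antisense_gene_in == "5utr" else "5'UTR"
        self.truth.planted_features.append(PlantedFeature(
            f"utr5_{locus_ids[0]}", utr5_iv, utr5_cls, locus_ids[0]))
        utr3_iv = self._map(left, footprint, strand, genes_end,
                            core + rt_len - 1)
        utr3_cls = "A_3'UTR" if antisense_gene_in == "rt" else "3'UTR"
        self.truth.planted_features.append(PlantedFeature(
            f"utr3_{locus_ids[-1]}", utr3_iv, utr3_cls, locus_ids[-1]))

        # TSS
        tss_pos = unit.interval.five_prime
        self._plant_tss(tss_pos, strand, unit)

        # operon
        self.truth.planted_operons.append(PlantedOperon(
            self._operon_id(), strand, tuple(locus_ids)))

        # opposite ncRNA inside a region of this operon
        if opposite_ncrna_in is not None:
            self._opposite_ncrna(left, footprint, strand, opposite_ncrna_in,
                                 u5, genes_end, core, gene_locals)

        return {"left": left, "footprint": footprint, "strand": strand,
                "u5": u5, "u3": u3, "core": core, "rt_len": rt_len,
                "unit": unit, "term": term, "genes": locus_ids,
                "gene_locals": gene_locals}

    def _effective_rt(self, rt_windows: int, depth: float | None,
                      profile: tuple[float, ...] | None) -> int:
        """Read-through windows that actually carry coverage under decay."""
        if not rt_windows:
            return 0
        cfg = self.cfg
        d = depth if depth is not None else 20.0
        prof = profile if profile is not None else (1.0,)
        peak = d * max(prof) * max(cfg.point_multipliers)
        n = 0
        for j in range(1, rt_windows + 1):
            decay = (1.0 - cfg.readthrough_decay) ** (cfg.read_length * j)
            if math.ceil(peak * cfg.readthrough_fraction * decay) < 1:
                break
            n = j
        return n

    def _singleton_operon(self, gene: GeneRecord) -> None:
        self.truth.planted_operons.append(PlantedOperon(
            self._operon_id(), gene.strand, (gene.locus_tag,)))

    def _opposite_ncrna(self, left: int, footprint: int, strand: str,
                        region: str, u5: int, genes_end: int, core: int,
                        gene_locals: list[tuple[int, int]]) -> None:
        if region == "gene":  # A_I: wholly inside the first gene body
            g_lo, g_hi = gene_locals[0]
            lo = g_lo + 100
            span = 250
        elif region == "5utr":  # A_5: wholly inside the 5'UTR
            lo = 100
            span = 250
        elif region == "3utr":  # A_3: wholly inside the 3'UTR
            lo = genes_end + 50
            span = 250
        elif region == "two_genes":  # A_misc: across both gene bodies
            (a1, b1), (a2, b2) = gene_locals[:2]
            lo = b1 - 149  # >= 150 nt into the first gene body
            span = (a2 + 150) - lo + 1
            span += (-span) % self.cfg.read_length
        else:
            raise ValueError(region)
        iv = self._map_opp(left, footprint, strand, lo, lo + span - 1)
        cls = {"gene": "A_I", "5utr": "A_5", "3utr": "A_3",
               "two_genes": "A_misc"}[region]
        self._standalone_ncrna(iv, cls)

    def _standalone_ncrna(self, iv: StrandedInterval, rna_class: str,
                          profile: tuple[float, ...] | None = None,
                          depth: float | None = None) -> None:
        unit = TranscriptionUnit(
            self._unit_id(), iv,
            depth if depth is not None else self._depth(),
            profile if profile is not None else self._profile())
        self.truth.transcription_units.append(unit)
        self.truth.expression_program[unit.unit_id] = tuple(
            unit.base_depth * f for f in unit.profile)
        fid = self._feat_id()
        self.truth.planted_features.append(PlantedFeature(fid, iv, rna_class))
        self.truth.expression_program[fid] = \
            self.truth.expression_program[unit.unit_id]
        self._plant_tss(iv.five_prime, iv.strand, unit)

    def indep_ncrna(self, strand: str,
                    profile: tuple[float, ...] | None = None) -> None:
        span = int(self.rng.choice((150, 200, 250, 300)))
        left = self._advance(span)
        iv = StrandedInterval(self.chrom, left, left + span - 1, strand)
        self._standalone_ncrna(iv, "indep", profile=profile)

    def readthrough_tandem(self, strand: str) -> None:
        """Two same-strand operons joined by terminator read-through; the
        gap region past the terminator is antisense to an opposite gene
        (class A_rt)."""
        cfg = self.cfg
        gap = 300  # window multiple; fully covered by read-through
        depth, profile = 40.0, PROFILE_ARCHETYPES["up_late"]
        if strand == MINUS:
            raise NotImplementedError(
                "read-through tandem is planted on the plus strand")
        up = self.operon(strand, 1, rt_windows=gap // cfg.read_length,
                         depth=depth, profile=profile)
        # rewind the inter-construct gap: the downstream operon starts
        # flush with the end of the read-through
        self.cursor = up["left"] + up["footprint"]
        self.operon(strand, 1, depth=depth, profile=profile)
        # opposite gene inside the read-through gap
        opp = MINUS
        rt_lo = up["left"] + up["core"]
        gene_iv = StrandedInterval(self.chrom, rt_lo + 40, rt_lo + 240, opp)
        self.genes.append(GeneRecord(self._gene_id(), "CDS", gene_iv))
        self._singleton_operon(self.genes[-1])
        # the A_rt feature: terminator end + 1 .. downstream 5'UTR start - 1
        self.truth.planted_features.append(PlantedFeature(
            self._feat_id(),
            StrandedInterval(self.chrom, rt_lo, rt_lo + gap - 1, strand),
            "A_rt"))
        # the upstream operon's 3'UTR truth already ends at the terminator?
        # operon() recorded it to core+rt; fix it to end at the terminator,
        # which is where the caller caps a read-through-masked 3'UTR.
        fixed = []
        for f in self.truth.planted_features:
            if f.feature_id == f"utr3_{up['genes'][-1]}":
                iv = StrandedInterval(f.interval.chrom, f.interval.start,
                                      up["left"] + up["core"] - 1, strand)
                fixed.append(PlantedFeature(f.feature_id, iv, "3'UTR",
                                            f.parent_gene))
            else:
                fixed.append(f)
        self.truth.planted_features = fixed

    def tandem_shift(self, strand: str) -> None:
        """Two contiguous transcripts with an 8-fold depth shift and an
        internal TSS but no terminator in between (operon split rule c)."""
        profile = PROFILE_ARCHETYPES["peak_mid"]
        up = self.operon(strand, 1, depth=10.0, profile=profile)
        # remove the terminator of the upstream unit: the downstream
        # transcript follows without interruption
        self.terminators = [t for t in self.terminators
                            if t.term_id != up["term"].term_id]
        # remove the upstream 3'UTR truth: its transcript runs straight
        # into the downstream unit, so no 3'UTR is assignable
        self.truth.planted_features = [
            f for f in self.truth.planted_features
            if f.feature_id != f"utr3_{up['genes'][-1]}"]
        if strand == PLUS:
            self.cursor = up["left"] + up["footprint"]
            self.operon(strand, 1, depth=80.0, profile=profile)
        else:
            raise NotImplementedError(
                "the expression-shift tandem is planted on the plus strand")

    def structural_block(self) -> None:
        """Unexpressed rRNA/tRNA genes with 600 nt promoter clearance."""
        specs = (("rRNA", PLUS, 1500), ("tRNA", MINUS, 80), ("tRNA", PLUS, 80))
        span = 600 + sum(ln + 600 for _, _, ln in specs)
        left = self._advance(span)
        pos = left + 600
        for kind, strand, ln in specs:
            iv = StrandedInterval(self.chrom, pos, pos + ln - 1, strand)
            gene = GeneRecord(self._gene_id(), kind, iv)
            self.genes.append(gene)
            self._singleton_operon(gene)
            pos += ln + 600

    def pseudo_gene(self) -> None:
        left = self._advance(500)
        gene = GeneRecord(self._gene_id(), "pseudo",
                          StrandedInterval(self.chrom, left, left + 499, PLUS))
        self.genes.append(gene)
        self._singleton_operon(gene)

    def _plant_tss(self, position: int, strand: str,
                   unit: TranscriptionUnit) -> None:
        self.truth.planted_tss.append(PlantedTss(
            position, strand, (), unit.active_points(self.cfg),
            unit.unit_id))

    # -- finalization -------------------------------------------------------

    def finalize(self) -> tuple[GenomeAnnotation, TruthTable]:
        ann = GenomeAnnotation(self.cfg.genome_length, circular=True,
                               chrom=self.chrom, genes=list(self.genes),
                               terminators=list(self.terminators))
        # fill in TSS classes by direct scan against the final annotation
        classed = [PlantedTss(t.position, t.strand,
                              _tss_classes_brute(t.position, t.strand, ann),
                              t.active_points, t.unit_id)
                   for t in self.truth.planted_tss]
        classed.sort(key=lambda t: (t.position, t.strand))
        self.truth.planted_tss = classed
        self.truth.planted_features.sort(
            key=lambda f: (f.interval.start, f.interval.strand))
        # guard: planted same-strand TSS stay resolvable (>= 40 nt apart)
        for s in (PLUS, MINUS):
            pos = sorted(t.position for t in classed if t.strand == s)
            if any(b - a < 40 for a, b in zip(pos, pos[1:])):
                raise ValueError("infeasible packing: planted TSS too close")
        return ann, self.truth


def _tss_classes_brute(position: int, strand: str,
                       ann: GenomeAnnotation, window: int = 500
                       ) -> tuple[str, ...]:
    """Direct per-gene scan: P/I/A classes, O iff none apply."""
    classes = set()
    for g in ann.genes:
        iv = g.interval
        if iv.contains(position):
            classes.add("I" if g.strand == strand else "A")
        if g.strand == strand:
            if strand == PLUS and iv.start - window <= position < iv.start:
                classes.add("P")
            if strand == MINUS and iv.end < position <= iv.end + window:
                classes.add("P")
    return tuple(sorted(classes)) if classes else ("O",)


# ---------------------------------------------------------------------------
# public generator API
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig
                    ) -> tuple[GenomeAnnotation, TruthTable]:
    """Plant the annotated genome and its ground truth.

    With ``gene_count == 0`` only independent intergenic ncRNAs are
    planted.  Otherwise the obligatory constructs (one instance of every
    RNA feature class, unexpressed structural RNAs, a pseudogene) are laid
    down first and ordinary operons fill the remaining gene budget.
    """
    rng_genome, _, _ = config.rngs()
    asm = _Assembler(config, rng_genome)

    if config.gene_count == 0:
        for strand, profile in ((PLUS, None), (MINUS, PROFILE_OFF_EARLY),
                                (PLUS, None)):
            asm.indep_ncrna(strand, profile=profile)
        return asm.finalize()

    minimum = _Assembler.SPECIAL_GENES + _Assembler.STRUCTURAL_GENES
    if config.gene_count < minimum:
        raise ValueError(
            f"infeasible packing: gene_count must be 0 or >= {minimum} "
            "(the obligatory feature-class constructs alone consume "
            f"{minimum} genes)")

    # obligatory constructs: one planted instance of every feature class
    asm.operon(PLUS, 1, u5=400, antisense_gene_in="5utr")       # A_5'UTR (+2)
    asm.operon(MINUS, 1, rt_windows=4, antisense_gene_in="rt")  # A_3'UTR (+2)
    asm.readthrough_tandem(PLUS)                                # A_rt (+3)
    asm.operon(PLUS, 1, opposite_ncrna_in="gene")               # A_I (+1)
    asm.operon(MINUS, 1, u5=400, opposite_ncrna_in="5utr")      # A_5 (+1)
    asm.operon(PLUS, 1, min_u3=400, opposite_ncrna_in="3utr")   # A_3 (+1)
    asm.operon(MINUS, 2, opposite_ncrna_in="two_genes")         # A_misc (+2)
    asm.indep_ncrna(PLUS)                                       # indep
    asm.indep_ncrna(MINUS, profile=PROFILE_OFF_EARLY)           # indep
    asm.tandem_shift(PLUS)                                      # (+2)
    asm.structural_block()                                      # (+3)
    asm.pseudo_gene()                                           # (+1)

    # filler operons up to the gene budget
    sizes = sorted(config.operon_size_probs)
    probs = [config.operon_size_probs[s] for s in sizes]
    remaining = config.gene_count - asm._n_gene
    while remaining > 0:
        n = int(asm.rng.choice(sizes, p=probs))
        n = min(n, remaining)
        strand = PLUS if asm.rng.random() < 0.5 else MINUS
        asm.operon(strand, n)
        remaining = config.gene_count - asm._n_gene

    return asm.finalize()


def default_sample_sheet() -> SampleSheet:
    """15 RNA-Seq samples (5 points x replicates L/R/M) plus the dRNA-Seq
    series of replicate L."""
    samples = {}
    for point in SAMPLING_POINTS:
        for rep in REPLICATES:
            samples[f"{rep}-{point}"] = SampleInfo(point, rep, "rnaseq")
        samples[f"d-L-{point}"] = SampleInfo(point, "L", "drnaseq")
    return SampleSheet(samples)


def simulate_rnaseq(annotation: GenomeAnnotation, truth: TruthTable,
                    config: SimulationConfig
                    ) -> dict[str, tuple[list[ReadAlignment], CoverageTrack]]:
    """Simulate the 15 RNA-Seq samples as reads + coverage tracks.

    Each transcript is tiled with adjacent 50-nt windows; a window at
    programmed mean depth ``m`` receives ``Poisson(m)`` identical stacked
    reads (noise on) or ``round(m)`` reads (noise off).  Read-through
    windows past a leaky terminator carry ``ceil(fraction * m)`` reads,
    attenuated by the configured geometric decay.
    """
    _, rng, _ = config.rngs()
    out: dict[str, tuple[list[ReadAlignment], CoverageTrack]] = {}
    L = annotation.genome_length
    for p_idx, point in enumerate(SAMPLING_POINTS):
        for rep in REPLICATES:
            sid = f"{rep}-{point}"
            reads: list[ReadAlignment] = []
            for unit in truth.transcription_units:
                mean = unit.point_mean(p_idx, config)
                for window, is_rt, rt_idx in unit.windows(config):
                    if is_rt:
                        m = unit.rt_depth(mean, rt_idx, config)
                        n = (rng.poisson(m) if config.poisson_noise
                             else math.ceil(m))
                    else:
                        m = mean
                        n = (rng.poisson(m) if config.poisson_noise
                             else _round_half_up(m))
                    reads.extend(ReadAlignment(window, sid)
                                 for _ in range(int(n)))
            if config.background_reads_per_sample > 0:
                n_bg = rng.poisson(config.background_reads_per_sample)
                for _ in range(n_bg):
                    start = int(rng.integers(1, L - config.read_length))
                    strand = PLUS if rng.random() < 0.5 else MINUS
                    reads.append(ReadAlignment(
                        StrandedInterval(annotation.chrom, start,
                                         start + config.read_length - 1,
                                         strand), sid))
            reads.sort(key=lambda r: (r.interval.strand, r.interval.start))
            out[sid] = (reads, coverage_from_reads(reads, L,
                                                   annotation.circular))
    return out


def simulate_drnaseq(annotation: GenomeAnnotation, truth: TruthTable,
                     config: SimulationConfig) -> dict[str, CoverageTrack]:
    """Simulate one dRNA-Seq coverage track per sampling point.

    Native 5' ends produce a sharp coverage plateau of width 30 starting
    exactly at each planted TSS that is active at the point; its height is
    the enrichment factor over the (optional) processed-end background.
    """
    _, _, rng = config.rngs()
    L = annotation.genome_length
    out: dict[str, CoverageTrack] = {}
    bg = config.drnaseq_background
    for point in SAMPLING_POINTS:
        track = CoverageTrack(L)
        if bg > 0:
            track.fwd += rng.poisson(bg, L)
            track.rev += rng.poisson(bg, L)
        height = config.drnaseq_enrichment * max(1, _round_half_up(bg))
        for tss in truth.planted_tss:
            if point not in tss.active_points:
                continue
            arr = track.activity(tss.strand)
            if tss.strand == PLUS:
                lo, hi = tss.position, min(tss.position + 29, L)
            else:
                lo, hi = max(1, tss.position - 29), tss.position
            arr[lo - 1:hi] += height
        out[point] = track
    return out


def random_sequence(length: int, seed: int) -> str:
    """Random A/C/G/T sequence (format validity and the ORF screen only)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xFA57A)))
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


# ---------------------------------------------------------------------------
# planted expression-profile groups (clustering benchmarks)
# ---------------------------------------------------------------------------

def simulate_profile_groups(n_features: int = 200, n_groups: int = 4,
                            noise_sd: float = 0.3, seed: int = 0
                            ) -> tuple[pd.DataFrame, np.ndarray]:
    """Z-scaled 5-point expression profiles drawn from planted groups.

    Each feature takes one of ``n_groups`` archetype profiles (z-scored)
    plus i.i.d. Gaussian noise of the given standard deviation.  Returns
    (profiles, labels) with features indexed f0000..; the group archetypes
    cycle through the module's expression archetypes.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC1457)))
    bases = []
    arch = [np.array(PROFILE_ARCHETYPES[k]) for k in sorted(PROFILE_ARCHETYPES)]
    for g in range(n_groups):
        a = arch[g % len(arch)].astype(float)
        if g >= len(arch):  # extra groups: shifted variants
            a = np.roll(a, g // len(arch))
        bases.append((a - a.mean()) / a.std())
    labels = rng.integers(0, n_groups, n_features)
    data = np.vstack([bases[l] + rng.normal(0.0, noise_sd, 5)
                      for l in labels])
    idx = [f"f{i:04d}" for i in range(n_features)]
    return pd.DataFrame(data, index=idx, columns=list(SAMPLING_POINTS)), labels
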