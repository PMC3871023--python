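"""End-to-end orchestration: simulate -> pool -> quantify -> TSS ->
features -> operons -> clustering, with one config, one seed and
deterministic outputs.

A single global seed is fanned out to per-stage seeds by a fixed
derivation, so identical configs give byte-identical output files and any
stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import expression_analysis as ea
from . import feature_annotator as fa
from . import operon_builder as ob
from . import quantify as qt
from . import tss_caller as tc
from .genome_model import (
    CoverageTrack,
    GenomeAnnotation,
    SampleSheet,
    read_annotation,
    read_coverage,
    read_reads,
    read_sample_sheet,
    read_terminators,
    write_annotation,
    write_coverage,
    write_reads,
    write_sample_sheet,
    write_terminators,
)
from .synthetic_data import (
    SimulationConfig,
    TruthTable,
    default_sample_sheet,
    generate_genome,
    random_sequence,
    simulate_drnaseq,
    simulate_rnaseq,
)

logger = logging.getLogger("regulome")

#: feature classes counted as non-coding RNAs (clustering input)
NCRNA_CLASSES = ("indep", "A_I", "A_5", "A_3", "A_misc")


def _derive_seed(seed: int, stage: int) -> int:
    """Fixed per-stage seed derivation from the global seed."""
    return int(np.random.SeedSequence((seed, stage)).generate_state(1)[0]
               % (2**31))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    seed: int = 1
    output_dir: str = "regulome_out"
    #: directory with real inputs (annotation.gff3, terminators.tsv,
    #: sample_sheet.tsv, coverage/, optionally reads/); None -> simulate
    input_dir: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # TSS calling
    min_ratio: float = 4.0
    pseudocount: float = 1.0
    structural_window: int = 500
    merge_window: int = 20
    min_support: int = 2
    promoter_window: int = 500
    drop_all_close_tss: bool = False
    # feature annotation
    orf_min_codons: int = 50
    utr_antisense_min: int = 100
    ncrna_antisense_min: int = 1
    internal_terminator_distance: int = 50
    readthrough_length: int = 1000
    abundance_split_factor: float | None = None
    # operons
    split_ratio: float = 4.0
    # quantification
    length_convention: str = "inclusive"
    # clustering
    p_thresh: float = 0.15
    min_points: int = 3
    min_npkm: float = 10.0
    cluster_k: int | None = None
    max_k: int = 8
    fom_restarts: int = 10
    kmeans_restarts: int = 25
    elbow_threshold: float = 0.10
    # output switches
    write_sample_coverage: bool = True
    write_read_beds: bool = False

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["simulation"]["operon_size_probs"] = {
            int(k): float(v)
            for k, v in d["simulation"]["operon_size_probs"].items()}
        d["simulation"]["point_multipliers"] = list(
            d["simulation"]["point_multipliers"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        sim = d.pop("simulation", {})
        if "point_multipliers" in sim:
            sim["point_multipliers"] = tuple(sim["point_multipliers"])
        return cls(simulation=SimulationConfig(**sim), **d)


@dataclass
class PipelineResult:
    config: PipelineConfig
    output_dir: Path
    annotation: GenomeAnnotation
    truth: TruthTable | None
    sheet: SampleSheet
    pooled: CoverageTrack
    tss: list[tc.TssRecord]
    features: list[fa.RnaFeature]
    operons: list[ob.Operon]
    gene_npkm: pd.DataFrame
    feature_npkm: pd.DataFrame
    clustering: ea.ClusteringResult | None
    retained_ncrnas: list[str]


# ---------------------------------------------------------------------------
# running
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write all outputs under config.output_dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> PipelineResult:
    stage = "setup"
    try:
        if config.input_dir is None:
            stage = "simulate"
            sim_cfg = replace(config.simulation,
                              seed=_derive_seed(config.seed, 1))
            annotation, truth = generate_genome(sim_cfg)
            rnaseq = simulate_rnaseq(annotation, truth, sim_cfg)
            drna = simulate_drnaseq(annotation, truth, sim_cfg)
            sheet = default_sample_sheet()
            sequence = random_sequence(annotation.genome_length, sim_cfg.seed)
            reads_per_sample = {sid: reads
                                for sid, (reads, _) in rnaseq.items()}
            tracks = {sid: track for sid, (_, track) in rnaseq.items()}
            _write_simulated_inputs(out, annotation, truth, sheet, sequence,
                                    rnaseq, drna, config)
        else:
            stage = "load"
            (annotation, truth, sheet, tracks, reads_per_sample, drna,
             sequence) = _load_inputs(Path(config.input_dir))

        stage = "pool"
        if reads_per_sample is not None:
            pooled = qt.pool_samples(reads_per_sample,
                                     annotation.genome_length,
                                     annotation.circular)
        else:
            logger.warning("no per-read input; pooling coverage without the "
                           "singleton filter")
            pooled = CoverageTrack(annotation.genome_length)
            for track in tracks.values():
                pooled.fwd += track.fwd
                pooled.rev += track.rev
        write_coverage(pooled, out / "pooled_plus.bedgraph",
                       out / "pooled_minus.bedgraph", annotation.chrom)

        stage = "tss"
        tss = tc.call_tss(drna, annotation, config.min_ratio,
                          config.pseudocount, config.structural_window,
                          config.merge_window, config.min_support,
                          config.promoter_window, config.drop_all_close_tss)
        logger.info("TSS: %d called, %d supported", len(tss),
                    sum(t.supported for t in tss))
        tc.write_tss_bed(tss, out / "tss.bed", annotation.chrom)
        tc.write_tss_tsv(tss, out / "tss.tsv")

        stage = "features"
        features = fa.annotate_features(
            pooled, annotation, tss, config.orf_min_codons, sequence,
            config.utr_antisense_min, config.ncrna_antisense_min,
            config.internal_terminator_distance, config.readthrough_length,
            config.abundance_split_factor)
        counts = fa.class_counts(features)
        logger.info("features per class: %s", counts)

        stage = "operons"
        operons = ob.predict_operons(annotation, pooled, tss,
                                     config.split_ratio)
        logger.info("operons: %d (sizes: %s)", len(operons),
                    sorted(len(o.genes) for o in operons))
        ob.write_operons(operons, out / "operons.tsv")

        stage = "quantify"
        gene_npkm = qt.npkm_matrix(annotation.genes, tracks,
                                   config.length_convention)
        feature_npkm = (qt.npkm_matrix(features, tracks,
                                       config.length_convention)
                        if features else pd.DataFrame())
        gene_npkm.rename_axis("gene").to_csv(out / "npkm_genes.tsv",
                                             sep="\t", float_format="%.4f")
        feature_npkm.rename_axis("feature").to_csv(
            out / "npkm_features.tsv", sep="\t", float_format="%.4f")
        npkm_max = feature_npkm.max(axis=1).to_dict() if len(feature_npkm) \
            else {}
        fa.write_feature_gff3(features, annotation, out / "features.gff3")
        fa.write_feature_table(features, out / "features.tsv", npkm_max)
        _write_class_summary(counts, out / "class_summary.tsv")

        stage = "clustering"
        clustering, retained = _cluster_ncrnas(config, features,
                                               feature_npkm, sheet, out)

        config.to_yaml(out / "config_effective.yaml")
        return PipelineResult(config, out, annotation, truth, sheet, pooled,
                              tss, features, operons, gene_npkm,
                              feature_npkm, clustering, retained)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _cluster_ncrnas(config: PipelineConfig,
                    features: Sequence[fa.RnaFeature],
                    feature_npkm: pd.DataFrame, sheet: SampleSheet,
                    out: Path) -> tuple[ea.ClusteringResult | None, list[str]]:
    nc_ids = [f.feature_id for f in features
              if f.rna_class in NCRNA_CLASSES]
    retained: list[str] = []
    if nc_ids:
        retained = ea.reliability_filter(
            feature_npkm.loc[nc_ids], sheet, config.p_thresh,
            config.min_points, config.min_npkm)
    logger.info("ncRNAs: %d called, %d reliable", len(nc_ids), len(retained))
    clustering = None
    if len(retained) >= 3:
        means = ea.point_means(feature_npkm.loc[retained], sheet)
        profiles = ea.zscore_profiles(means)
        if len(profiles) >= 3:
            k_range = range(1, min(config.max_k, len(profiles) - 1) + 1)
            clustering = ea.cluster_profiles(
                profiles, seed=_derive_seed(config.seed, 2),
                k=config.cluster_k, k_range=k_range,
                fom_restarts=config.fom_restarts,
                kmeans_restarts=config.kmeans_restarts,
                elbow_threshold=config.elbow_threshold)
            ea.write_clusters(clustering, out / "clusters.tsv")
            ea.write_centroids(clustering, out / "centroids.tsv")
            if clustering.fom is not None:
                ea.write_fom(clustering.fom, out / "fom.tsv")
    if clustering is None:
        logger.info("too few reliable ncRNAs for clustering")
        (out / "clusters.tsv").write_text("feature\tcluster\n")
    return clustering, retained


def _write_class_summary(counts: Mapping[str, int], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("rna_class\tcount\n")
        for cls in fa.RNA_CLASSES:
            fh.write(f"{cls}\t{counts.get(cls, 0)}\n")


def _write_simulated_inputs(out: Path, annotation, truth, sheet, sequence,
                            rnaseq, drna, config: PipelineConfig) -> None:
    write_annotation(annotation, out / "annotation.gff3")
    write_terminators(annotation.terminators, out / "terminators.tsv",
                      annotation.chrom)
    write_sample_sheet(sheet, out / "sample_sheet.tsv")
    truth.to_json(out / "truth.json")
    with open(out / "genome.fasta", "w") as fh:
        fh.write(f">{annotation.chrom}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i:i + 70] + "\n")
    if config.write_sample_coverage:
        cov_dir = out / "coverage"
        cov_dir.mkdir(exist_ok=True)
        for sid, (_, track) in sorted(rnaseq.items()):
            write_coverage(track, cov_dir / f"{sid}_plus.bedgraph",
                           cov_dir / f"{sid}_minus.bedgraph",
                           annotation.chrom)
        for point, track in sorted(drna.items()):
            write_coverage(track, cov_dir / f"d-L-{point}_plus.bedgraph",
                           cov_dir / f"d-L-{point}_minus.bedgraph",
                           annotation.chrom)
    if config.write_read_beds:
        reads_dir = out / "reads"
        reads_dir.mkdir(exist_ok=True)
        for sid, (reads, _) in sorted(rnaseq.items()):
            write_reads(reads, reads_dir / f"{sid}.bed")


def _load_inputs(input_dir: Path):
    """Real-data mode: read annotation, coverage and optional reads."""
    annotation = read_annotation(input_dir / "annotation.gff3")
    terms_path = input_dir / "terminators.tsv"
    if terms_path.exists():
        annotation.terminators = read_terminators(terms_path)
    sheet = read_sample_sheet(input_dir / "sample_sheet.tsv")
    truth_path = input_dir / "truth.json"
    truth = TruthTable.from_json(truth_path) if truth_path.exists() else None
    tracks, drna = {}, {}
    for sid, info in sheet:
        plus = input_dir / "coverage" / f"{sid}_plus.bedgraph"
        minus = input_dir / "coverage" / f"{sid}_minus.bedgraph"
        track = read_coverage(plus, minus, annotation.genome_length)
        if info.assay == "drnaseq":
            drna[info.sampling_point] = track
        else:
            tracks[sid] = track
    reads_dir = input_dir / "reads"
    reads_per_sample = None
    if reads_dir.is_dir():
        reads_per_sample = {p.stem: read_reads(p)
                            for p in sorted(reads_dir.glob("*.bed"))
                            if p.stem in tracks}
    fasta = input_dir / "genome.fasta"
    sequence = None
    if fasta.exists():
        lines = fasta.read_text().splitlines()
        sequence = "".join(l.strip() for l in lines if not l.startswith(">"))
    return annotation, truth, sheet, tracks, reads_per_sample, drna, sequence


# ---------------------------------------------------------------------------
# evaluation against planted truth
# ---------------------------------------------------------------------------

def evaluate_against_truth(result: PipelineResult | str | Path,
                           truth: TruthTable | None = None,
                           tolerance: int = 20) -> dict:
    """Recovery metrics of a synthetic run against its planted truth.

    Returns a dict with TSS recall/precision (positional tolerance 20 bp),
    the feature class confusion matrix and accuracy, boundary-error
    statistics, and operon partition agreement.
    """
    if isinstance(result, (str, Path)):
        out = Path(result)
        if truth is None:
            truth_path = out / "truth.json"
            if not truth_path.exists():
                raise FileNotFoundError(f"missing truth table {truth_path}")
            truth = TruthTable.from_json(truth_path)
        tss = tc.read_tss_tsv(out / "tss.tsv")
        features = fa.read_feature_table(out / "features.tsv")
        operons = _read_operons(out / "operons.tsv")
    else:
        if truth is None:
            truth = result.truth
        if truth is None:
            raise ValueError("no truth table available")
        tss, features, operons = result.tss, result.features, result.operons

    metrics: dict = {}

    # TSS recovery
    called = [(t.position, t.strand) for t in tss if t.supported]
    planted = [(t.position, t.strand) for t in truth.planted_tss]
    hit = [any(s == ps and abs(p - pp) <= tolerance for pp, ps in planted)
           for p, s in called]
    recovered = [any(s == ps and abs(p - pp) <= tolerance
                     for pp, ps in called) for p, s in planted]
    metrics["tss_called"] = len(called)
    metrics["tss_planted"] = len(planted)
    metrics["tss_recall"] = (sum(recovered) / len(planted)) if planted else 1.0
    metrics["tss_precision"] = (sum(hit) / len(called)) if called else 1.0

    # feature classes and boundaries
    confusion: dict[tuple[str, str], int] = {}
    n_correct = 0
    boundary_errors = []
    for pf in truth.planted_features:
        best, best_ov = None, 0
        for f in features:
            if f.strand != pf.interval.strand:
                continue
            ov = max(0, min(f.interval.end, pf.interval.end)
                     - max(f.interval.start, pf.interval.start) + 1)
            if ov > best_ov:
                best, best_ov = f, ov
        called_cls = best.rna_class if best else "missed"
        confusion[(pf.rna_class, called_cls)] = \
            confusion.get((pf.rna_class, called_cls), 0) + 1
        if best is not None and called_cls == pf.rna_class:
            n_correct += 1
        if best is not None:
            boundary_errors.append(max(
                abs(best.interval.start - pf.interval.start),
                abs(best.interval.end - pf.interval.end)))
    n_planted = len(truth.planted_features)
    metrics["features_planted"] = n_planted
    metrics["features_called"] = len(features)
    metrics["class_accuracy"] = n_correct / n_planted if n_planted else 1.0
    metrics["boundary_error_mean"] = (float(np.mean(boundary_errors))
                                      if boundary_errors else 0.0)
    metrics["boundary_error_max"] = (float(np.max(boundary_errors))
                                     if boundary_errors else 0.0)
    metrics["confusion"] = confusion

    # operon partition agreement
    from sklearn.metrics import adjusted_rand_score

    pred_labels = ob.operons_to_partition(operons)
    true_labels: dict[str, int] = {}
    for i, op in enumerate(truth.planted_operons):
        for tag in op.genes:
            true_labels[tag] = i
    common = sorted(set(pred_labels) & set(true_labels))
    if common:
        ari = adjusted_rand_score([true_labels[t] for t in common],
                                  [pred_labels[t] for t in common])
        pred_sets = {frozenset(op.genes) for op in operons}
        true_sets = {frozenset(op.genes) for op in truth.planted_operons}
        exact = len(pred_sets & true_sets) / len(true_sets)
    else:
        ari, exact = 1.0, 1.0
    metrics["operon_ari"] = float(ari)
    metrics["operon_exact_fraction"] = float(exact)
    metrics["operons_predicted"] = len(operons)
    metrics["operons_planted"] = len(truth.planted_operons)
    return metrics


def write_metrics(metrics: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for k in sorted(metrics):
            if k == "confusion":
                continue
            fh.write(f"{k}\t{metrics[k]}\n")
        for (true_cls, called_cls), n in sorted(
                metrics.get("confusion", {}).items()):
            fh.write(f"confusion:{true_cls}->{called_cls}\t{n}\n")


def _read_operons(path: Path) -> list[ob.Operon]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            oid, strand, genes, _n, ptss, term = line.rstrip("\n").split("\t")
            out.append(ob.Operon(oid, strand, tuple(genes.split(",")),
                                 int(ptss) if ptss else None, term or None))
    return out
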