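# Methods

This note records the models, conventions and parameter choices behind
`regulome`, and what the synthetic benchmark does and does not show.

## Coordinates and formats

Internally every interval is 1-based, inclusive on both ends, with an
explicit strand and `start <= end`. Publication-style tables encode the
minus strand by printing start > stop; that convention is applied only in
the table writer/reader, so feature lengths are always
`end − start + 1`. bedGraph I/O uses the format's 0-based half-open
intervals, converted solely inside the readers/writers. The chromosome is
circular; reads may wrap the origin, but the generator leaves the origin
region empty so no in-scope rule depends on wrapping.

## NPKM

NPKM(n, m) = 1e9 · Σ_{i=n..m} f(i) / (G · len), with f(i) the
strand-specific base activity and G the genome-wide total activity over
both strands. Two deliberate choices:

* **Denominator scope.** G is the library size (total mapped
  nucleotides), not a region-bounded sum — a region-bounded denominator
  would not normalize for sequencing depth and would break the "per
  million mapped" semantics NPKM inherits from RPKM.
* **Length factor.** `len = m − n + 1` by default, matching the inclusive
  length convention used everywhere else; the alternative `m − n` is
  available as `length_convention="printed"` for compatibility with the
  bare difference form of the formula.

rRNA/tRNA-mapping reads can be removed before G is computed
(`quantify.mask_structural_reads`), mirroring experimental rRNA
depletion; the synthetic structural RNAs are unexpressed, so the mask is
a no-op on the benchmark.

## Pooling filter

Within each sample, a read is dropped iff its whole span has coverage
exactly 1 and no same-strand read overlaps or directly abuts it
(end + 1 = next start counts as contact). The filter is idempotent and
runs per strand in O(n log n) by sorted sweep. Its purpose is to keep
unreplicated single reads from bridging or extending features during
segmentation.

## TSS calling

* **Step rule.** Candidate iff ln((cov(p)+1)/(cov(up)+1)) > ln 4, with
  `up` the upstream neighbor in transcription direction (p−1 on `+`,
  p+1 on `-`). The pseudocount of 1 bounds the statistic when the
  upstream base has zero coverage (a raw ratio would be infinite) and
  converges to the plain ratio at high coverage.
* **Structural mask.** Candidates within 500 bp upstream of, or inside,
  a same-strand rRNA/tRNA gene are removed (their promoters dominate
  dRNA-Seq signal without marking mRNA starts).
* **Merging.** Chains of same-strand candidates pairwise closer than
  20 bp keep only the strongest member (ties break to the smaller
  coordinate). Keep-the-strongest was chosen over drop-all because 5'
  ends show micro-heterogeneity; drop-all is available
  (`drop_all=True`).
* **Cross-point support.** The same 20 bp window matches sites across
  sampling points — one positional-resolution parameter pipeline-wide.
  The consensus position is the one from the point with the largest
  step; sites seen in ≥ 2 points are flagged supported. All downstream
  consumers (UTR masking, operon rule c) use supported sites only.
* **Classes.** P/I/A are each assigned whenever applicable (one site may
  be P and I at once); O is assigned exactly when none of the three
  applies.

## Feature discovery and the ten classes

Segmentation takes maximal runs of strictly positive pooled coverage per
strand; one zero base ends a run ("clearly separated" is operationalized
as a zero-coverage gap).

**5'UTR.** For each protein-coding gene whose start codon lies inside a
segment, the UTR runs from the segment's 5' rise to the base before the
start codon — the longest supportable candidate. If the segment extends
into or through an upstream same-strand gene (read-through masking), the
most-upstream *supported* TSS in the intergenic gap becomes the boundary;
without such a TSS no 5'UTR is called, so internal operon genes get a
5'UTR only on internal-promoter evidence.

**3'UTR.** Symmetrically, from the base after the stop codon to the
segment's fall to zero. If the segment runs into a downstream same-strand
gene, the UTR is capped at the most-downstream intrinsic terminator fully
inside the intergenic gap; with no terminator there, no 3'UTR is
assignable. Terminator status: `at_terminator` when a terminator's 3'
end lies within 50 nt of the transcript end, `internal_terminator` when
one lies ≥ 50 nt upstream; internal termination plus a UTR longer than
1000 nt (configurable) sets the read-through flag.

**A_rt.** When a 3'UTR was capped at a gap terminator, the remaining
region up to the downstream transcript's 5' boundary is an intergenic
read-through segment; it becomes an `A_rt` feature iff antisense to a
gene (≥ 1 nt), otherwise it is logged and dropped. This is the package's
mechanization of a class that was originally curated by hand; the
defining geometry — read-through past a terminator, before the next
transcript, opposite a gene — is preserved.

**ncRNAs.** Segments clear of same-strand genes and UTRs are candidates
with boundaries at the first/last nonzero base. Classification is by
containment: `indep` (no opposite-strand gene or UTR contact), `A_I`
(wholly inside exactly one opposite gene body, no UTR contact), `A_5` /
`A_3` (wholly inside exactly one opposite 5'/3'UTR, no gene contact),
`A_misc` (everything else: multiple targets or partial overlap). The
minimum antisense overlap for ncRNA classes is 1 nt — the class
definitions are categorical — while UTRs switch to `A_5'UTR`/`A_3'UTR`
only when overlap to a single opposite gene *exceeds* 100 nt (100 is not
enough).

Candidates containing a same-strand ORF of ≥ 50 codons are flagged, not
dropped — a lightweight screen standing in for protein-database searches,
preserving the audit trail instead of silently deleting candidates. An
opt-in abundance-contrast splitter (`abundance_split_factor`, default
off) cuts a segment between adjacent 50-bp windows whose mean coverage
differs more than 10-fold, mechanizing the manual separation of highly
abundant ncRNAs embedded in mRNA transcripts.

## Operons

Same-strand genes adjacent in genome order are scanned in transcription
order; a pair is split by the first matching rule: (a) a zero-coverage
base in the intergenic gap, (b) a terminator fully within the gap, (c) a
supported TSS in the gap or the upstream gene's 3' half combined with a
pooled-NPKM fold change > `split_ratio` (default 4, deliberately the same
fold-change scale as the ln 4 TSS step). The rule order is this
package's convention; external operon predictions can veto joins via
`join_veto` but are never required. The output is a partition: every
gene, including unexpressed ones, belongs to exactly one operon.

## Expression clustering

* **Reliability screen.** Per sampling point, a two-sided one-sample
  t-test of the replicate NPKMs against zero; the feature needs
  P < 0.15 in ≥ 3 of 5 points and max NPKM > 10. The test design is a
  replicate-consistency screen: tight replicates pass, erratic ones
  fail. Zero-variance replicates are resolved analytically (P = 0 for a
  nonzero mean, else 1). A between-point Welch variant is exposed
  (`test="welch"`) for users who prefer a differential screen. Points
  with fewer than two replicates cannot contribute and are logged.
* **Z-scoring.** Per-feature standardization of the five point means
  (population sd); zero-variance rows are dropped with a warning since
  they carry no profile shape.
* **FOM.** Leave-one-condition-out: for each k, cluster on four points,
  score the root-mean-square deviation of the left-out point from its
  cluster means, adjust by sqrt(n/(n−k)), sum over left-out points.
  The selected k is the largest whose relative improvement over k−1
  still reaches 10% — curves can plateau briefly before the real drop,
  so the last adequate improvement, not the first stall, marks the
  elbow. k can always be overridden (`cluster_k`).
* **k-means.** Euclidean, best of 25 restarts, features processed in
  sorted-id order so labels are invariant to input row order under a
  fixed seed.

## Synthetic data generator

The generator emulates the target study design: a circular chromosome
(default 150 kb, 48 genes) with operons of mostly 1–2 genes
(size probabilities 0.65/0.20/0.10/0.05 for 1–4), each transcribed from a
TSS 20–300 nt upstream of its first gene through a 3'UTR ending in a
30-bp intrinsic terminator; expression follows four archetype profiles
over sampling points I–V (late induction, decline, mid peak, mid valley)
at base depths of 10–80×, under a 5-point × 3-replicate design with one
dRNA-Seq series. One instance of every one of the ten feature classes is
planted explicitly, including a leaky terminator reading through over an
opposite gene (A_3'UTR), a terminator read-through bridge between two
same-strand operons across an opposite gene (A_rt), and a contiguous
tandem with an internal TSS and an 8-fold depth shift (operon rule c).
Unexpressed rRNA/tRNA genes (with 600 nt promoter clearance) and a
pseudogene exercise the structural mask.

Reads are stranded 50-nt intervals tiled in adjacent windows, so
noise-free coverage equals the programmed depth exactly at every
transcribed base and planted boundaries are recoverable to the base; with
noise on, each window draws Poisson(mean) stacked reads. Read-through
past a leaky terminator carries ceil(0.1 × depth) with optional
geometric per-base decay (default 0: constant, with an explicitly planted
extent). dRNA-Seq tracks put a 30-nt plateau of height 20× background at
each active TSS and nothing else (background configurable).

What this does **not** emulate: nucleotide-level biology (sequences are
random and used only for format validity and the ORF flag), sequencing
error, positional bias, transcript-internal coverage roughness, 5'-end
micro-heterogeneity, and processed-RNA contamination of dRNA-Seq.
Perfect recovery on the benchmark therefore validates the boundary/class
logic and the arithmetic, not robustness to real-library artifacts. The
default benchmark sizes (150 kb genome, ~35 transcription units, 20
coverage tracks) were chosen so a full run takes seconds while every rule
in the pipeline fires at least once.

## Determinism and numerics

One global seed is fanned out to per-stage seeds through
`numpy.random.SeedSequence`, so identical configs give byte-identical
output files (the config echo records the output path and differs when
runs are written to different directories). Coverage is held as dense
int64 vectors — exact arithmetic, no floating-point accumulation. The
NPKM of an empty library (G = 0) raises rather than returning NaN.
k-means ties and empty-cluster events are handled by scikit-learn's
restart machinery; FOM at k = 1 reduces to the RMS deviation from the
column mean.

## Known limitations

* Operon adjacency is scanned linearly; a gene pair spanning the origin
  of the circular chromosome is not joined.
* The A_rt rule requires a terminator between the two transcripts; true
  terminator-less read-through antisense regions end up inside a long
  3'UTR instead.
* The reliability screen's t-test against zero is scale-free and will
  pass any feature with consistently nonzero replicates, however weak;
  the NPKM > 10 floor is what keeps weak features out.
* With Poisson noise at very low depth (mean < ~3) a window can draw
  zero reads and split a segment; the benchmark uses depths ≥ 10 where
  this is negligible.
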