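# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open. Conversion happens only
at file boundaries: SAM POS (1-based inclusive) on input, wiggle
positions (1-based) and the CLI's `--region chrom:start-end` (1-based
inclusive) on output/input. A single internal convention eliminates
off-by-one drift between the counting, pileup and export paths.

## Gene models and counting

A gene is its chromosome, strand and exon list; the normalizing length
`L` is the exon *union* (overlapping exons counted once), the standard
RPKM convention. Strand is recorded but never affects counting or
coverage: counting is unstranded.

A read is assigned to a gene by its **start position** falling inside
the exon union. This mirrors the start-sorted, start-only read
representation that makes per-gene counting a pair of binary searches
per exon rather than an overlap scan; a read that starts in an exon and
runs into an intron still counts once, toward that gene. When genes
overlap, a read starting in the exons of several genes counts toward
each of them (no fractional assignment).

A junction read contributes to a gene only when *both* of its anchor
blocks overlap (by at least one base) some exon of the gene; this
prevents read-through junctions from being credited to a neighboring
gene. Junction-mapper BED output aggregates reads per junction, so a
positive score column is read as the supporting-read count
(`count_mode="score"`, the default); `count_mode="one"` counts each
record once for BED files whose score is not a count.

"Uniquely mapped" follows the dominant aligner convention: the NH tag
decides when present (unique iff NH == 1); otherwise MAPQ > 0.
Secondary and supplementary records (flags 0x100/0x800) are dropped
before the uniqueness test. Paired-end mates count as separate reads —
no fragment collapsing — so RPKM and FPKM coincide here.

The per-sample depth `N` is the number of uniquely mapped exon-aligned
reads plus the total junction support, i.e. every uniquely mapped read
including those rescued by the junction mapper.

## Signal maps

Coverage at a base is the number of unique reads whose
reference-consuming CIGAR blocks cover it: M/=/X cover; N (skipped
intron) and D (deletion) advance the reference without covering —
the usual pileup convention. Whole chromosomes use an event sweep
(+1 at each block start, −1 at each end, prefix sum), linear in reads
plus chromosome length; windows use binary search on read starts with a
max-span bound to prune candidates. Junction BED reads are *not* part
of signal maps — maps are built from SAM/BAM alignments only — since
anchor blocks are junction summaries, not per-base alignments.
Group-averaged and differential (mean(A) − mean(B)) tracks are
double-precision; raw tracks are integers.

## Change-point model

For a signal sequence x of length n, the null model is one Gaussian
with unknown mean and variance (2 free parameters); the single-change
alternative at split k fits both halves separately (4 parameters).
With ML (divide-by-n) variances, SIC = −2·max-log-likelihood +
(parameters)·ln n gives

    SIC0   = n ln(2π σ̂²) + n + 2 ln n
    SIC(k) = n ln(2π) + k ln σ̂₁² + (n−k) ln σ̂₂² + n + 4 ln n

Each variance is floored at ε = 1e−8 so exactly-constant segments stay
finite; the floor only matters for noise-free inputs. Admissible splits
keep at least `min_seg = 10` bases on each side (both ε and min_seg are
CLI-tunable). The SIC(k) profile is computed for all k at once from
prefix sums of x and x².

Detection is binary segmentation: accept k* = argmin SIC(k) iff
SIC(k*) < SIC0 for the segment, recurse into both sides, stop when
nothing is accepted, segments are shorter than 2·min_seg, or `max_cp`
(default 10) splits are found. This handles an unknown number of change
points at O(n log n)-ish cost instead of an exhaustive multi-change
search.

Reporting: raw segment-level SIC values are not comparable across
segments of different lengths (SIC scales with n), so every accepted
position is re-scored by its *full-interval* single-split SIC. Positions
whose full-interval SIC does not beat the interval's SIC0 are dropped,
the rest are listed in ascending SIC order, and an interval's evidence
is `SIC0 − min SIC` — which for intervals holding a single change point
equals the acceptance margin of the first split. UTR ranking sorts
intervals by this evidence, descending; intervals with no accepted
change point are excluded. Results are independent of the order
intervals are processed in, so scanning parallelizes trivially.

Calibration: the bare SIC rule (accept when the best of ~n correlated
split candidates beats a 2 ln n penalty) has an empirical false-positive
rate of about 7–8% on pure N(0,1) noise at n = 500 (7.4% over 1000
replicates); a 100-replicate draw therefore fluctuates by a few points.
A 3σ mean shift in the middle of n = 500 is recovered within ±10 bases
essentially always.

## Synthetic data generator

The generator emulates the study conditions end to end: two 50 kb
chromosomes; 20 genes of three 200-base exons separated by 300-base
introns, laid out round-robin with 500-base intergenic gaps; 10 000
single-end 50-base reads per sample, of which 10% are junction reads
(the fraction typical of mammalian RNA-seq), 5% multi-mapped (NH:i:2,
MAPQ 0) and 5% unmapped (flag 0x4); three samples. Class counts are
allocated exactly (rounded fractions of n_reads), so e.g. 10 000 reads
at `frac_junction = 0.1` give exactly 1 000 junction-read supports.
Unique exon reads start uniformly over the exon union of a uniformly
chosen gene; junction reads anchor on the adjacent-exon pair of a
multi-exon gene, half the read length on each side, and are aggregated
into BED12 records whose score is the support count. One PCG64 stream
per sample, spawned from the master seed, makes outputs byte-identical
for a fixed seed and keeps gene layout independent of read noise.

The planted 3'-UTR drop-out (`dropout = (gene_id, utr_fraction,
amplitude)`) removes each unique read starting in the trailing
`utr_fraction` of the gene span with probability `amplitude`; the truth
TSV records the counts actually emitted. Track-level planted signals
(`simulate_differential_utr_map`) inject a mean shift of chosen
amplitude into the trailing 40% of one UTR of a Gaussian-noise
differential map — a faster, exactly-placed stand-in for simulating two
read-level groups when only the change-point stage is under test.

What the generator does **not** emulate: sequencing errors and quality
scores, non-uniform (biased) coverage, isoform structure, overlapping
genes, paired-end fragments, and real junction-mapper imperfections.
Passing tests therefore demonstrate algorithmic correctness against
oracles under idealized placement, not robustness to real-library
artifacts.

## Numerical and design choices

- Sorting/merging of SAM/BAM is an explicit stable sort (Timsort) /
  k-way heap merge on (header chromosome index, start, input index);
  stability — equal keys keep input order — is part of the contract,
  which generic coordinate sorters do not promise.
- RPKM cells are exact IEEE-754 ratios; the TSV prints 4 decimals.
- Wiggle export writes `variableStep ... span=1` with zero suppression
  (sparse-friendly, browser-compatible); reals get up to 4 decimals,
  integers no decimal point; chromosome blocks follow input (header)
  order so output is byte-deterministic. Only that dialect is read back.
- Duplicate gene ids across loci become `id_locus1`, `id_locus2`, ...
- Degenerate inputs: empty SAM files load as empty samples; an empty
  annotation classifies everything intergenic; an all-zero differential
  map yields an empty ranking; `rpkm()` refuses N = 0 or L = 0.
- Problem sizes in tests and the acceptance script (10⁴–10⁶ reads,
  50 kb chromosomes, 100-replicate simulations, n ≤ 2 000 exhaustive
  change-point scans) are chosen so each stage's oracle comparison
  runs in seconds while still exercising the asymptotic behavior.

## Known limitations

- Gene-level only: no isoform deconvolution, no GTF/GFF input.
- Fold change is the only between-condition statistic; no significance
  testing or normalization beyond RPKM/FPKM.
- Start-position counting undercounts genes relative to overlap-based
  counters when reads straddle the first exon boundary from outside.
- The SIC false-positive rate is a property of the penalty, not a
  user-set α; use the reported delta for ranking rather than as a
  calibrated p-value.
- BigWig, bedGraph and BAI indexing are out of scope.
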