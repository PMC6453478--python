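# Methods

## Overview

`dogcatcher` finds and quantifies read-through transcription around
annotated genes in stranded RNA-seq data. Four geometries are called per
gene: sense signal past the 3' end (DoG, "downstream-of-gene" transcript),
antisense signal past the 3' end (ADoG), and the sense/antisense analogues
upstream of the 5' end (PoG/APoG). Downstream of discovery, a
negative-binomial GLM with an interaction design scores whether each
region's IP/input ratio differs between two conditions — the natural test
for RIP-seq experiments (e.g. J2 dsRNA immunoprecipitation) where
"enrichment" must be measured against both an input fraction and a
reference condition.

## Coordinates and data model

All internal coordinates are 0-based half-open; conversion happens only at
file boundaries (GTF is 1-based closed; BED/bedGraph share the internal
convention). Coverage is stored per (chromosome, strand) as canonical
run-length segments: sorted, non-overlapping, zero-depth runs dropped,
adjacent equal-depth runs merged. Canonical form makes coverage equality
and bedGraph round-trips exact, which the determinism guarantees below rely
on.

## Flattening

Overlapping same-strand gene models are merged into maximal *blocks*
(connected components of the interval-overlap graph, computed by a sweep).
Genes that merely touch (end == next start) also merge: the scan cannot
host signal in a zero-length gap, so distinguishing them would be
meaningless. Discovery anchors at block edges, not gene edges, so a short
gene nested inside a longer host yields a read-through region that starts
at the end of the host — the behaviour needed to interpret, e.g., an
ncRNA inside a protein-coding gene whose read-through invades the next
locus.

## The window scan

From the anchor (block 3' end for DoG/ADoG, 5' end for PoG/APoG; signal
strand equal to the block strand for the sense categories and opposite for
the antisense ones), the scanner examines consecutive non-overlapping
windows moving away from the gene.

Parameters (defaults):

| parameter          | default | meaning                                            |
|--------------------|---------|----------------------------------------------------|
| `window`           | 100 bp  | window size; the step equals the window            |
| `min_depth` (tau)  | 1.0     | per-base depth threshold                           |
| `min_covered_frac` | 0.8     | fraction of window bases required at depth >= tau  |
| `mode`             | local   | behaviour at same-signal-strand genes              |
| `max_extent`       | 50 kb   | hard cap on scan distance                          |

A window passes when at least `min_covered_frac x window` of its bases
have depth >= tau. The covered-fraction criterion was chosen over a
mean-depth criterion because it is robust to single-base pileups; a 100-bp
window with one 1000x spike and 99 empty bases should not pass. Extension
stops at the first failing window, at `max_extent`, or when no full window
remains before the chromosome end. In *local* mode a window touching a
gene on the signal strand stops the scan and the region is truncated at
that gene's proximal edge; in *meta* mode such windows are treated as
passing, the gene is recorded, and scanning continues beyond it (for
quantifying read-through that runs across entire downstream genes). The
candidate region is finally trimmed inward to the last base at depth >=
tau, so a passing-but-ragged final window never pads the call with up to
`window - 1` empty bases. Anchors at a chromosome edge yield no call.

Non-overlapping stepping makes the scan O(n/window) with a worst-case
distal boundary error of one window, which the planted-region tests
confirm (anchored end exact, distal end within 100 bp). A step-1 sliding
variant would reduce the distal error but is O(n x window); the window
step is the deliberate default.

In meta mode, bases belonging to skipped genes are excluded from the
region's `mean_depth`, so the reported depth reflects intergenic
read-through signal rather than the skipped gene's own expression.

## Post-discovery filters

Three rules, applied in order, with every removal attributed in a log:

1. DoGs overlapping an operon on the same strand are removed —
   polycistronic transcription through an operon is expected, not
   termination failure (relevant for *C. elegans*-style annotations).
2. PoGs overlapping a surviving same-strand DoG are removed — the
   "upstream" signal is just the upstream neighbour's read-through.
3. ADoGs and APoGs overlapping, on their signal strand, a gene or a
   surviving DoG on that strand are removed — the antisense signal is
   explained by transcription already annotated or called there.

Operons are supplied either as GTF features of a configurable type or as
BED6; the matching rule is any >= 1 bp same-strand overlap.

A gene is reported as *overlapped* (receiving antisense read-through) when
an ADoG is anchored to its own block or a DoG on the opposite strand
intersects the gene body.

## Counting

Feature counts are estimated from coverage as
`round(depth-sum / read_length)` (half-up), on the feature strand or, for
antisense quantification, the opposite strand. For uniformly tiled reads
this equals the read count exactly; the synthetic read-placement test
holds it within 2% on 10k-read fixtures. Externally produced count
matrices are accepted wherever counts are consumed, so a BAM-based counter
can be substituted without touching the statistics layer.

## Normalization

Two size-factor families, both centred to geometric mean one:

* **RSR (rRNA-subtraction-ratio)** — effective depth
  `d_i = total_mapped_i - rrna_mapped_i`, factor `s_i = d_i / geomean(d)`.
  Used when per-library read accounting is available, in particular for
  designs where IP libraries retain rRNA while inputs are depleted, which
  would otherwise skew total-count scaling.
* **Median-of-ratios** — the classic pseudo-reference scheme on features
  with all-positive counts, falling back to total-count scaling (with a
  warning) when no such feature exists.

*Padded normalization*: novel regions are few and often condition-specific,
so size factors and the dispersion trend estimated on them alone would be
unstable. `padded_lrt` concatenates annotated gene counts with the region
counts, estimates factors and dispersions on the combined matrix, tests
everything, then reports only the regions, with BH adjustment restricted
to them. Gene rows never appear in the output.

## The NB-GLM interaction LRT

Per feature, counts follow a negative binomial with log link and offset
`log(s_i)`:

    log mu_i = b0 + b_cond x_cond + b_frac x_frac + b_int x_cond x_frac

with treatment coding (reference condition and input fraction as
baselines). The likelihood-ratio statistic between this model and the one
without `b_int` is referred to chi-square(1); `log2FC = b_int / ln 2` is
the log2 change of the IP/input ratio in the condition relative to the
reference. The engine is a specified NB-GLM, not a DESeq2
re-implementation: no Cox-Reid adjustment, no fold-change shrinkage.

Dispersion is estimated per feature by method of moments on normalized
counts using within-cell means and variances (so real design effects do
not inflate it), floored at 1e-8, then shrunk 50/50 toward the mean
dispersion of the feature's expression decile — a lightweight
empirical-Bayes stand-in for a fitted trend. Designs without replication
fall back to a fixed dispersion of 0.1. GLM fitting is IRLS
(statsmodels), tolerance 1e-8, 100 iterations; non-converged or degenerate
features (e.g. an all-zero design cell) are conservatively reported with
p = 1. All-zero features carry a `log2Mean = -inf` sentinel and are
excluded from BH.

Significance classes follow the FDR-plus-expression-floor convention:
*enriched* iff FDR < 0.05, log2Mean > 4 and log2FC > 0; *depleted* with
log2FC < 0; otherwise *ns*. log2Mean is the log2 mean normalized count
over the contrast samples.

Calibration, measured by the acceptance suite on 2000 null features
(phi = 0.05, 2x2x3 design): empirical type-I error ~0.06-0.075 at nominal
0.05 across seeds, and p-values consistent with uniformity by KS test.
The mild anticonservativeness is the expected small-sample behaviour of an
unpenalized LRT at n = 12; a Bartlett-type correction is deliberately out
of scope.

Two structural limits of this engine are worth knowing (both verified
numerically and asserted honestly in the acceptance suite):

* With n = 3 per cell the 2x2 model is saturated, so the interaction MLE
  is the cell-mean log ratio-of-ratios; its standard deviation is
  `sqrt(4 (1/mu + phi) / 3) / ln 2 >= 0.37` log2 units at phi = 0.05 no
  matter how deep the counts. About 77-82% of estimates land within
  +-0.5 of a planted log2FC; no unbiased estimator can do materially
  better at these settings. Detection is unaffected (sensitivity ~1.0,
  empirical FDR well under 0.05 at the default thresholds).
* The raw-count likelihood is only asymptotically invariant to jointly
  scaling one library's counts and its size factor: a deeper library
  carries more Poisson-level information (IRLS weight mu/(1+phi mu)).
  Deviations are O(1/(phi mu)) — ~5e-4 in p at mu = 1e4 and up to ~0.07
  at low counts. Normalized quantities (log2Mean) are exactly invariant.

When measuring estimator accuracy against planted truth, size factors are
fixed at the generative truth (unit depth): estimating median-of-ratios
factors on a matrix where a quarter of features carry a one-directional 8x
effect absorbs ~0.26 log2 of the signal into the factors (compositional
bias, shared by all median-of-ratios tools), which is a property of
normalization, not of the estimator under test.

## Ratio and overlap statistics

*Antisense/sense ratios*: per gene,
`log2[(anti+c)/(sense+c)]_cond - log2[(anti+c)/(sense+c)]_ref` with
pseudocount c = 1, computed on input libraries (pooled across replicates
per condition in the pipeline). Genes are scored only when the pooled mean
of the four count vectors is >= 20, an expression floor that keeps
near-zero ratios out. Tallies of ratio/sense/antisense changes use strict
`> 0`; ties are not "up".

*Set overlap*: upper-tail hypergeometric `P(X >= k)`, symmetric in the two
sets. The population is a caller-supplied universe; the pipeline uses the
intersection of features scored in both contrasts. P-values depend
strongly on this choice — with a different universe convention, absolute
p-values are not comparable.

*Repeat enrichment*: the observed statistic is the number of regions
intersecting at least one repeat; the null redraws length-matched
intervals uniformly inside a supplied background (intergenic space, same
chromosome), with slots weighted by the number of valid placements.
Empirical p uses the add-one rule, `(1 + #{null >= obs}) / (1 + n)`, so it
is never zero and is bit-reproducible for a fixed seed.

## Synthetic studies

The generator builds the package's entire test bed, emulating the
structure of a stranded RNA-seq + RIP-seq experiment:

* **Genome**: alternating-strand genes (0.5-2 kb) with 1.5-4 kb intergenic
  gaps on 100-kb chromosomes; with probability `operon_prob` the next gene
  continues on the same strand after a 20-60 bp gap and the pair is
  recorded as an operon.
* **Coverage**: gene bodies at a constant depth on their own strand;
  planted read-through regions extend from the proper anchor with a given
  depth, decaying linearly to zero over the final 100 bp so that distal
  boundary recovery is non-trivial. Plantings can be condition-specific
  and/or IP-enriched (depth x 2^log2FC in the condition IP fraction).
  Optional Poisson resampling of every base adds replicate-to-replicate
  variation.
* **Counts**: NB draws with per-feature lognormal baseline means
  (sigma = 1 natural-log unit around 100, emulating the dynamic range of
  expression) and a planted interaction effect in the condition IP cell.

All randomness flows from a single seed split into named substreams
(genome / coverage / counts), so each product is reproducible in
isolation and the whole study is byte-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: splice structure and junction reads,
fragment-length effects, GC/mappability bias, overdispersion of coverage
along a region (depth is piecewise-deterministic unless Poisson noise is
on), polyA-site heterogeneity, and genuinely overlapping transcription on
the same strand beyond simple containment. Numbers produced on synthetic
studies validate the algorithmic contracts, not biological effect sizes.

## Pipeline

`dogcatcher run` executes: parse/flatten -> per-sample discovery and
filtering -> cross-sample union per category (a region is tested if called
in >= 1 sample; coordinates are the union span; per-sample calls are also
written so alternative merge policies can be audited) -> counting (genes
sense/antisense plus regions, per sample) -> RSR-normalized padded LRT per
category and gene-level tests -> classification -> antisense/sense ratio
summary and overlapped-gene report. Every output is plain TSV/JSON; a
manifest records sha256 checksums, and reruns with the same config and
seed are checksum-identical. `--resume-from {discover,count,enrich,stats}`
reloads earlier stages' outputs from disk.

Problem sizes used by the shipped demo and the acceptance script — 16
genes on two 100-kb chromosomes, 2x2 design with two replicates, six
planted regions; 50 scenarios for recovery; 2000/2000 features for
calibration and estimator measurements — were chosen so the whole suite
exercises every code path at desk scale while remaining statistically
meaningful for the quantities asserted.

## Known limitations

* Unstranded libraries are out of scope; the method is strand-specific by
  construction.
* Splice-aware read-through (a DoG spanning an intron of a downstream
  gene) is not modelled; coverage is treated as genomic.
* The discovery scan calls at most one region per (block, category); two
  blocks with a short gap can produce overlapping DoGs, which are both
  reported rather than deduplicated (the removal log and per-sample tables
  make downstream policy auditable).
* The NB engine's p-values are approximate at very low counts (see
  calibration above); borderline calls near the FDR threshold should not
  be over-interpreted.
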