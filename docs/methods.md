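# Methods

## Setting and model

The package assumes the two-platform design common to cell-line dosage
studies: each of a small cohort of tumor lines (default 4) has a per-SNP
copy-number state track from a genotyping array, coded 0 (homozygous
deletion), 1 (heterozygous deletion), 2 (diploid), 3 (single-copy gain),
4 (amplification), at ~23.6 kb mean probe spacing; and an expression
matrix of normalized intensities for tumor replicates (default 3 per
line) against healthy-tissue controls (default 10).  Upstream genotype
calling, HMM segmentation and RMA normalization are out of scope — the
state tracks and intensities are inputs.

All genomic coordinates are 1-based closed throughout; only BED
import/export converts to 0-based half-open.  Chromosome names are
normalized to `chr`-prefixed form.  Band-boundary ties (possible only in
externally supplied maps) resolve to the lower-coordinate band.

## Copy-number regions

A **CNA** is a maximal run of consecutive altered probes of one direction
within a chromosome; a lone altered probe is a single-SNP CNA.  Runs break
on direction change so that every CNA carries a single gain/loss label;
states 3 and 4 (and 0 and 1) are merged for run construction and kept
apart only in composition summaries.  The CNA interval spans the first and
last member probe positions, not the flanking diploid probes.

An **MRR** is a maximal interval where every sample has an overlapping
CNA, computed by a coverage sweep over the per-sample CNA interval unions
(equivalent to the n-way intersection).  Intervals with zero probes are
dropped; by default an MRR must also contain ≥ 1 probe altered in every
sample (both the sample-count threshold and the recurrent-probe
requirement are arguments).  Direction need not agree across samples:
discordant support yields the `combined` label.  Per-region summaries
report size, probe counts, the mean log2 ratio over member probes ×
samples, and a one-sample t-test of those ratios against 0 as −log10 p
(0 for the degenerate all-equal case).

## Gene mapping and the accounting table

Genes attach to regions by *any* span overlap (partial coverage counts).
Per sample, a gene's class is the direction of the overlapping CNA; if
CNAs of both directions overlap, the larger-overlap CNA wins (ties to
gain — rare and only possible with adjacent opposite runs).  Separately,
the altered probes *inside* the gene span are counted per sample: inside a
CNA most genes have zero probes of their own, which is exactly why the
trend statistics below are informative.

The dosage-vs-expression table mirrors the field's accounting convention:
per-sample counts of explored CN+ / CN− genes and how many of each are
deregulated, an average row whose percentages are ratios of the *averaged
counts* (not means of percentages), and a recurrent-genes row (CN-altered
in all samples, any direction) compared against all remaining explored
genes using the pooled all-lines DE calls.  Per-line DE calls can be
supplied as a DataFrame; unexplored genes never enter denominators.

## Differential expression

SAM-style two-class unpaired statistics, re-implemented rather than
wrapped: d_i = (mean_T − mean_C)/(s_i + s₀) with s_i the pooled standard
error and s₀ a quantile (default median) of the s_i distribution.
Significance is calibrated by label permutations (default 200): observed
order statistics are compared with their permutation means, cut points
derived per delta, and FDR estimated as the median permuted count beyond
the cuts over the observed call count.  The working delta is the smallest
achieving the target FDR (default 0%); if none does, the minimizing delta
is used and flagged.  A windowed local-FDR estimate (permuted vs observed
density in a ±1 window on the d axis) approximates the local-FDR < 10%
side condition.  Final calls require the fold-change cut-off (1.5 and its
exact reciprocal — 0.66 is a display rounding) *and* the delta criterion;
a gene with FC = 2 that misses the delta stays `unchanged`, as does one at
FC = 1.45 with a large d.  Everything is deterministic given the config
seed.

## Enrichment statistics

The 2×2 chi-square uses the closed form
N(|ad−bc| − N/2)²/((a+b)(c+d)(a+c)(b+d)) with the Yates continuity
correction **on** by default: the correction is required to reproduce the
anchor values p = 0.0035 (147/783 vs 2,975/19,958) and 4.5×10⁻⁶ (28/64 vs
147/783) from the printed counts.  Zero margins or expected counts < 5
fall back to Fisher's exact test, flagged in the output.  The per-MRR
deregulation test compares each region against the whole-set totals
*including* the tested region (again required by the anchor value;
exclusion is an option).

PAGE operates on the signed log2 fold-change axis by default so that up-
and downregulated sets are symmetric (ratios 1.5 and 1/1.5 map to
±0.585); raw ratios are a switch.  μ and δ are always computed over the
full deregulated set; sets with fewer than 10 deregulated genes are
reported but not scored.  No multiple-testing adjustment is applied by
default (Benjamini–Hochberg available as an extra column) — raw p-values
mirror the analysis convention this package replicates.

## Trends and clustering

The linear-by-linear (Mantel–Haenszel) statistic is computed from binned
counts as M² = (N−1)r², r the Pearson correlation of integer bin scores
(1..k, equally spaced) with the binary outcome over all N units; p from
the df = 1 chi-square tail.  Default bins: region size {1–100, 101–500,
>500 SNPs}; per-gene altered-SNP load {0, 1, 2–5, 6–20, >20} — the
per-gene edges are not canonical, so they include a 0-probe bin (the
dominant class inside CNAs) and are configurable.  The downregulation
trend reports Spearman correlations both at bin level (bin rank vs
downregulated fraction; exactly flat fractions return ρ = 0, p = 1 by
definition) and at unit level (altered-SNP count vs the binary
downregulation indicator).

Cluster analysis finds maximal runs of ≥ 2 contiguous deregulated genes in
genomic order; runs may mix up and down genes.  The randomness test is a
formalization of "different from a random arrangement": the expected
number of clustered deregulated genes under random placement is estimated
by Monte-Carlo permutation of the status sequence (default 5,000 draws,
seeded), followed by a df = 1 goodness-of-fit chi-square on clustered vs
unclustered deregulated counts; when an expected cell is < 1 the
Monte-Carlo exceedance probability replaces the chi-square p.  The
exceedance p is reported alongside in all cases.

## Validation calculators

qPCR copy number: normalized value = target/reference quantity (or
efficiency^−ΔCt in Ct mode, efficiency 2 unless supplied); copy number =
2 × normalized(sample)/median(normalized controls), so a control at the
median reads exactly 2.  qRT-PCR expression normalizes to the median of
the reference assays and reports fold change against the control mean.
FISH ratio = mean target signals / mean control signals, warning below the
20-nucleus convention.  Cross-platform correlation is per-gene Pearson r
over ≥ 3 shared samples, NA on zero variance.  All calculators are
invariant to the units of the raw quantities.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the pipeline
measures: Poisson-process SNP spacing matched to the 23.6 kb array mean;
planted gain/loss regions with configurable recurrence across samples and
configurable continuity (the fraction of in-region probes actually set
altered); log2-ratio tracks consistent with the states; lognormal
expression with dosage-driven upregulation, a repressed fraction, a
partial-silencing slope (P(down) rising with the gene's mean per-sample
altered-probe load in discontinuous regions), and spatial autocorrelation
of deregulation along the gene order via a latent AR(1) field.  Planted
regions always leave ≥ 1 diploid probe between one another so they can
never fuse into one CNA run, which makes exact-boundary recovery a
well-posed check.

Deliberately not emulated: probe-level array artifacts and GC waves,
heterogeneous real probe maps, tumor subclonality, per-line heterogeneity
of effects (lines share each gene's planted effect), and isoform
structure.  Passing tests therefore demonstrate correctness of the
algorithms and statistics under the assumed generative structure, not
robustness to real-array noise.

Default scale: 3 chromosomes × 50 Mb, ~6,300 probes, 600 genes, 40
planted regions, 4 lines × 3 replicates vs 10 controls.  This is the
package's chosen desk scale: large enough that every statistic operates
in its asymptotic regime, small enough that the full suite and the
acceptance script run in seconds.  The trend-recovery experiments use a
larger design (2,000 genes, 120 kb median gene length, continuity 0.5,
silencing slope 0.10/SNP) so that the in-region unit count (~500–800)
matches the scale at which the Spearman trend is conventionally assessed.

## Numerical and design choices

* Genome-wide totals of the original study (e.g. 1,065 CNAs, 108 MRRs,
  19.2% altered genome) derive from the full 116K-probe arrays and are
  covered by property-based recovery on synthetic data, not by numeric
  replication; the printed-count statistics above are replicated exactly.
* The exact SAM 3.0 internals (s₀ search by coefficient-of-variation
  minimization, spline local FDR) are intentionally simplified; the
  contract is the cut-off behaviour, and both knobs are exposed.
* Chi-square vs Fisher agreement is a sanity property only away from the
  extreme tail; deep-tail p-values from the corrected chi-square can
  differ from the exact test by tens of percent in relative terms even at
  large expected counts.
* All pipeline randomness (permutations, Monte-Carlo, simulation) flows
  from a single seed, split deterministically per stage; identical config
  + seed gives byte-identical outputs.

## Known limitations

Single-threaded; per-gene Python loops in the mapper are fine at array
scale (~20K genes) but not for exome-density probe sets.  The DE caller
assumes two groups and unpaired samples.  MRR identification requires at
least two samples and treats the cohort symmetrically — no weighting by
line.  The cluster test conditions on the observed status counts and gene
order, so it cannot detect clustering that manifests only in effect sizes.
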