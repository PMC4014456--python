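# Methods

## Scope and model

`histolink` implements a sire→offspring epigenetic-concordance analysis
in three statistical stages — differential histone-association calling
from tiling-array signal in sperm, differential expression (DE) in
individual 2-cell embryos, and contingency tests of gene-list overlap —
plus a generative model of the study that makes every stage testable
end to end.  The biological model encoded by the simulator: most gene
promoters retain a low level of nucleosomes in mature sperm; a
chromatin perturbation in a male shifts retention up at some loci
(MAT+) and down at others (MAT−); only a fraction of his sperm express
the aberrant states (variegation); each embryo inherits the states of
exactly one sperm; and a carried aberrant locus perturbs zygotic
expression with a per-locus linkage probability, depleted loci biasing
expression up (precocious activation) and enriched loci down.

## Synthetic-data generator

**Genome.**  `n_genes` loci (default 2,000 for desk-scale runs; the
19,472-gene microarray universe is available via config) on
`n_chroms` chromosomes.  Each gene has a promoter abutting the TSS and
a gene-body interval (0-based, half-open throughout).  Baseline
promoter occupancy is log-odds-normal with three couplings: +0.8
log-odds per GC class step, −1.2 log-odds per unit promoter
methylation, and residual spread 0.5; occupancies are rescaled so
their mean equals the configured genome-wide retention level (default
0.01, the order observed in mouse sperm).  Gene-body probes sit 1.5
log-odds below the promoter, reproducing the promoter > CDS enrichment
contrast.

**Probe track.**  20 promoter probes and 8 gene-body probes per gene,
25-mers spaced 50 bp — a scaled-down version of the dense tiling of
commercial promoter arrays (which tile at ~35 bp), chosen so a 600-bp
window holds ~12 probes.  The MNase-channel intensity is linear in the
log2-odds of the *population-mean* occupancy at the probe (monotone,
bounded, invertible — the simplest link consistent with signal
proportional to the fraction of sperm retaining a nucleosome), plus
iid Gaussian log2 noise (sd 0.25); the input channel is
occupancy-independent noise around a fixed offset.  The finite sperm
population (default 10^5 sperm per sample) enters as binomial sampling
of per-locus retention.

**Perturbation and variegation.**  Perturbed males draw per-gene states
once: MAT+ with probability 0.10 and MAT− with 0.14 (matching the
scale of per-male differential calls of roughly 2,300 enriched and
3,000 depleted genes out of ~22,000 interrogated).  The aberrant
occupancy (±3 log2-odds by default) is expressed in only
1 − `frac_unaffected_sperm` of sperm; the unaffected fraction defaults
to 0.30, inside the 25–35% range reported by per-sperm
protamine-deficiency staining.  Variegation is a two-component mixture
(affected/unaffected sperm); continuous severity is not modeled.  A
consequence worth noting: depletion signal saturates at
log2(`frac_unaffected_sperm`) ≈ −1.7 log2 units however large the
shift, so MAT− calls are intrinsically harder than MAT+ — the
asymmetry is a feature of the biology, not of the caller.

**Embryos.**  One sperm per embryo, drawn uniformly (no selection
bias).  Affected sperm carry all of the sire's aberrant states.  Each
carried aberrant locus outside the maternal class becomes truly DE with
probability `p_link` (default 0.05, reflecting that only a minority of
sperm histone aberrations can change embryo expression; per-embryo DE
counts were ~0.2–2% of genes while ~20% of genes were aberrant per
male).  Expression = per-gene baseline (maternal ≈ 2^7, zygotic ≈ 2^6,
silent ≈ 2^2) + ±`de_effect` (default 1.5 log2; reported validation
folds ranged ~1.7–11×) + iid log2 noise.  The noise sd of 0.065
reproduces the ~4.5% control coefficient of variation seen on real
single-embryo arrays.  Maternal-class genes (30% of the genome; the
zygotic class is 25%) are never linked to the paternal state.

**Determinism.**  All draws flow from one seed through fixed
`SeedSequence` spawn keys per stage/male/embryo, so outputs — including
the plain-text fixture files — are byte-identical across runs and
independent of generation order.

**What the generator does *not* emulate:** probe-sequence effects (GC
bias, cross-hybridization), spatial array artifacts, correlated noise
between neighboring probes, amplification distortion of single-embryo
RNA, allele-specific expression, and any real genomic coordinates.
Passing tests therefore demonstrate the *statistical* correctness and
calibration of the pipeline under the declared model, not performance
on any particular real array platform.

## Tiling enrichment

Normalization is RMA-style: optional per-sample background subtraction
at a configurable percentile (off by default — the generator is
background-free; the option exists for real scanner data), quantile
normalization, log2.  Quantile normalization is applied **within
channel class** (`.mnase` columns together, `.input` columns together):
the two channels have genuinely different distributions and forcing
them onto a common one erases the enrichment signal.  Probe-level
analysis throughout; median-polish summarization is deliberately not
applied to tiling probes.

The window statistic follows the published sliding-window construction
at desk scale: per-probe two-sample T (Welch when both groups have ≥2
samples; for 1-vs-1 comparisons the per-probe difference standardized
by a robust global scale, the only estimable analogue), window score =
10%-trimmed mean of member probe statistics × √n_probes over 600-bp
windows stepped 100 bp with ≥4 probes.  Window membership requires
non-decreasing probe ends per chromosome (true for fixed-length tiling
probes); irregular geometries are rejected rather than silently
approximated.

Window p-values: the default permutation null randomly sign-flips the
per-probe statistics (≥1,000 seeded flips), rescores all windows and
pools the null scores; for 1-vs-1 comparisons label permutation is
degenerate (two labelings), so the Gaussian-tail fallback is used —
scores standardized by their genome-wide median/MAD (robust to the
~25% of truly shifted genes) and referred to a normal tail.  Windows at
p < 0.01 of consistent sign merge within 300 bp (half a window);
opposite-sign windows do not break a same-sign chain.  Regions annotate
genes by ≥1-bp overlap with the gene extent (promoter ∪ body), strand
ignored (the arrays are strandless).

A male's differential set intersects the per-sign calls over every
pairwise comparison against individual controls — intersection rather
than union suppresses single-control artifacts at the cost of
sensitivity; the pooled `all_vs_all` mode compares group means with the
permutation null.  Measured on the default synthetic conditions:
≥95% of true MAT± genes recovered at default thresholds, and a
gene-level false-call rate ≈ 0.5% under the null generator (below the
nominal 1%, as the intersection rule is conservative).

## Embryo DE

With a single experimental sample per comparison, the only estimable
contrast is one-vs-group: t = (x − mean(controls)) / (sd(controls) ·
√(1 + 1/n)) with n − 1 degrees of freedom, requiring ≥3 controls.
Benjamini–Hochberg runs within each embryo-vs-pool comparison (not
across embryos).  The ratio is defined on log2 means
(2^(embryo − control mean)); Cv uses the sample (n−1) standard
deviation on linear-scale values, since the Cv of log values is
scale-ambiguous.  Genes with control Cv > 5% are flagged but retained.

## Concordance

The 2×2 table of membership in list A × membership in list B over the
universe is tested with Pearson χ² (1 df) and Yates' correction
(|O − E| reduced by 0.5 per cell, clamped at zero).  The significance
verdict uses the more conservative of the two p-values and additionally
requires observed > expected — a one-directional guard that rejects
strong *depletion* of overlap.  φ = √(χ²_Pearson/N), sign negative when
observed exceeds expectation (source convention; `phi_convention=
"textbook"` flips it).  Expected overlap is reported unrounded, with
half-up display rounding.  When any expected cell is below 5, a Fisher
exact p is attached with a warning; exhaustive enumeration of all 2×2
tables with N ≤ 60 shows ≥95% verdict agreement between the χ² rule and
Fisher at α = 0.05.  Genes carrying both MAT+ and MAT− calls appear in
both sign strata; the combined MAT−/+ stratum deduplicates.  α = 0.05
is fixed and no multiplicity correction is applied across grid cells —
a known limitation inherited from the analysis design, stated here so
grid-wide significance counts are read as descriptive.

## qPCR

Delta-delta-Ct with technical replicates averaged (arithmetic mean of
Ct) before ΔCt = Ct(target) − Ct(reference); fold =
2^(ΔCt_group2 − ΔCt_group1), so fold > 1 means higher expression in
group 1; 100% PCR efficiency assumed.  One two-sided Student t per gene
contrast on per-sample ΔCt; outlier replicates are not dropped.

## Numerical choices and degenerate inputs

Quantile normalization resolves ties by averaging tied quantiles.
Zero-variance control genes get a 10⁻¹² sd floor (p ≈ 1 when the
difference is 0).  Degenerate 2×2 margins (empty or universe-sized
lists) return χ² = 0, p = 1, not significant.  A zero MAD falls back to
the standard deviation, then to unscaled differences.  Region merging
breaks ties deterministically via stable sorts; all tabular outputs are
written with round-trippable float repr so bundles are byte-stable.

## Problem sizes

Default test and acceptance runs use the 2,000-gene genome with 3 + 3
males, 3 embryos per male, 56,000 probes and ~20 simulation replicates
for calibration/recovery properties — sizes chosen so the full suite
exercises every pipeline path at genome-like density while remaining
quick on a laptop.  The 19,472-gene universe is used wherever the
published list sizes are the input (overlap arithmetic), where the
computation is closed-form and size-independent.

## Known limitations

MAT− sensitivity is bounded by the variegation floor (above).  The
Gaussian-tail null is approximate for very small window counts; the
permutation null is preferred whenever group sizes allow.  Quantile
normalization distorts when a large asymmetric fraction of the genome
shifts (an assumption violation shared with any rank-based
normalization, visible in the simulator at extreme occupancy shifts).
The pipeline ingests summarized expression tables only; no CEL parsing,
read mapping, or GO enrichment (ranked gene lists are exported for
external tools).
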