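# Methods

## Region-summative methylation

A region's methylation level pools counts before dividing: ml =
Σ #C / Σ(#C + #T) over all CpGs in the region and all selected samples.
This is deliberately a ratio of sums, not a mean of per-sample ratios, so
high-coverage CpGs carry proportionally more weight and a region's level is
invariant to how sites are partitioned (the union of disjoint regions
equals count-weighted pooling of the parts — a tested invariant). CpG sites
enter only if every sample in both compartments covers them with more than
5 reads (strict inequality). Zero-coverage regions return NaN, never 0, and
are excluded downstream.

Compartment contrast uses Hyper = log2((ml_GLOM + β)/(ml_TI + β)) with
β = 0.001. The pseudocount bounds the statistic at ±log2(1.001/0.001) ≈
±9.97 for fully unmethylated regions; at moderate levels it perturbs the
ratio by < 1%. Differential testing is a two-sided Welch t-test on
per-sample pooled region levels — Welch rather than pooled-variance because
compartment variances differ in practice — with Benjamini–Hochberg
correction by default and Bonferroni selectable.

## Dip calling

Dips are called on pooled TI methylation evaluated in fixed windows
(default 10 bp; CpG-level data are too sparse for per-base evaluation).
Maximal runs of windows with ml ≤ 0.4 are reported when they span ≥ 50 bp.
Windows without covered CpGs are undefined and break runs: a low region
interrupted by a coverage gap is reported as its covered fragments, not
bridged. Called dips are therefore maximal, disjoint, and grid-aligned;
equality with a per-base sliding-scan brute force is asserted over random
tracks in the test suite.

## Gisch filter and chromatin states

The Gisch filter compares a region's signal AUC with the whole-gene AUC,
both as per-base densities — comparing a raw summed AUC with a "gene
average" is only scale-consistent after length normalization (raw mode is
available). Peak mode requires strictly greater density, dip mode strictly
less; ties are "absent".

State classification is a pure function of mark presence (≥ 1 bp overlap
with the mark's peak set) and location, applied in order: H3K4me3⁺ H3K27ac⁺
in a promoter → active promoter (H3K4me1 free either way); H3K4me1⁺
H3K27ac⁺ without H3K4me3 outside promoters → predicted enhancer; remaining
H3K27me3⁺ → repressed; else unclassified. The enhancer rule has a strict
variant that additionally excludes gene bodies; the permissive variant is
the default so intronic enhancers are admitted. The four outcomes are
mutually exclusive and exhaustive by construction.

## Agreement statistics

Region units for coding are the gene's promoter, upstream block, exons and
introns, position-sorted, with all technologies coded over the identical
unit list. Cohen's kappa uses the standard (p_o − p_e)/(1 − p_e); when both
vectors are constant, chance agreement is degenerate and the limit
convention applies (identical → 1, opposite → −1, flagged). G_T is the
unweighted mean kappa across genes. Fisher association uses the
conventional two-sided definition (summing all tables no more probable than
the observed one) on fixed-width bins, 1 kb by default; odds ratios with a
zero cell are reported Haldane-corrected while the p-value always comes
from the uncorrected table.

## Cell-state analyses

Accessibility is binarized at count > 0 ("possessing open chromatin" as a
per-cell predicate). The DA test is the 1-df likelihood-ratio test of a
logistic regression of group on accessibility against the intercept-only
null. With a single binary covariate the fitted model is saturated on the
2×2 table, so the statistic is computed in closed form (the G-statistic);
agreement with an iteratively fitted logistic regression is asserted in the
tests. Fold changes use log2((f_a + ε)/(f_b + ε)) with ε = 0.001 — small
enough to barely perturb moderate fractions while avoiding log 0. DE uses
the two-sided Wilcoxon rank-sum test on counts normalized to 10,000 per
cell and log1p-transformed, testing genes expressed in > 2% of either
group, Bonferroni-corrected. New peaks are DA peaks whose down-group has
strictly < 2% accessible cells. Gene-level open chromatin sums
accessible-cell fractions over peaks fully inside the TSS ± 5 kb window
plus any peak overlapping the TSS base (containment is the stricter,
reproducible reading of "within 5 kb").

Deconvolution replaces the original mixture algorithm with nonnegative
least squares renormalized onto the simplex; the scientific content here is
the signature construction (top 10% of each type's markers, kept only with
a histone promoter peak, ≥ 20 surviving markers per retained type), not the
solver.

## Best-fit expression model

Per category, a univariate regression of expression log2FC on Hyper across
genes records the genome-wide Pearson r. Categories with negative r form
the candidate set; each gene takes the candidate minimizing its absolute
standardized residual (genes with no finite candidate fall back to the most
negative-r category); the combined predictions are summarized by the
concordance index (ties count 0.5). One caveat this package documents
explicitly: the per-gene selection is in-sample model selection, so under a
true null (expression independent of methylation) the c-index of the
combined predictions sits above 0.5 when several candidate categories
exist; the ≈ 0.5 null holds for any fixed single-candidate model, and both
behaviors are asserted in the tests.

## The synthetic generator

The generator emulates the study's observables at desk scale: two 1 Mb
chromosomes, 50 genes in fixed slots, 4 samples per compartment, three cell
types × 300 nuclei, binomial bisulfite counts at Poisson coverage (mean
30), methylation levels 0.15/0.85, Bernoulli accessibility, Poisson
expression with 10% dropout, and expression log2FC = −Hyper(causal region)
+ N(0, (0.25 × signal sd)²). At this scale the full pipeline runs in about
two seconds; the acceptance computations use 200 genes on six chromosomes
where recovery statistics need them.

Design choices that make the planted truth identifiable (and which real
data do not guarantee):

- CpG density varies by element: 10 bp spacing in CpG-dense promoter
  blocks, gene-body islands and enhancers; 20 bp in the upstream promoter
  half; 30 bp in introns; 100 bp in exons and upstream blocks; 300 bp in
  open sea. Dense elements are aligned to the dip-calling grid and sparse
  CpGs keep one window clear of them, so called dip boundaries coincide
  exactly with planted regions — real dips have ragged boundaries.
- The dense promoter block sits strictly upstream of the TSS and exon 1
  spans the downstream promoter half, so the four causal categories
  (promoter, CpG island, exon, intron) move nearly disjoint CpG pools.
  Real promoters and first exons share CpGs, which would blur category
  attribution.
- GLOM/TI direction assignments are balanced within each causal category;
  without this the category regressions acquire intercept offsets from sign
  imbalance and even noiseless recovery degrades.
- Marker boost mass is balanced exactly between the two compared cell
  states, and 450 background transcriptome genes keep markers a small
  fraction of each library. Otherwise library-size normalization converts
  planted-null genes into apparent DE (a compositional artifact real
  atlases mitigate by transcriptome breadth).
- Chromatin states have exact stratified counts and cell-type markers are
  drawn ~60% from active-promoter genes so the signature's promoter-peak
  rule never starves a type.

Passing recovery tests on this generator therefore demonstrates that the
implementations compute what they claim under a model where the signal is
planted and identifiable — not that the thresholds would perform equally on
tissue data with batch structure, covariate-driven accessibility, or
correlated regions.

## Numerical and degenerate-input conventions

Zero-variance equal-mean groups give t = 0, p = 1; constant methylation
columns are excluded from the best-fit model; degenerate Fisher margins
give p = 1 with an undefined odds ratio; rank-deficient signatures warn and
return the minimum-norm solution; all-zero mixture estimates fall back to
uniform before renormalization. All randomness flows from one seed through
fixed per-stage stream offsets, making every output byte-reproducible; ties
in interval ordering are broken by (chrom, start, end).

## Default problem sizes

Tests and the acceptance script use: 1000 null regions with 15 samples per
compartment for Welch calibration (the WGBS study's group size, where the
test is well calibrated; at 4 samples per group Welch is conservative,
rejecting at ≈ 0.040); 2000 null peaks × 10 seeds for the Bonferroni
family-wise guarantee; 200 genes × 20 seeds for causal-category recovery;
10 seeds for DE recovery; 20 seeds for mixture recovery. These sizes keep
the whole suite to a few minutes while leaving the Monte-Carlo margins
interpretable.
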