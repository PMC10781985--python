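# epichrom

Integration of the kidney's regulatory landscape across assays: whole-genome
bisulfite methylation of microdissected glomerular (GLOM) and
tubulointerstitial (TI) compartments, histone-mark (H3K4me3, H3K4me1,
H3K27ac, H3K27me3) and open-chromatin peak sets, and single-nucleus
peak-by-cell / gene-by-cell matrices contrasting a healthy reference
epithelial state with an adaptive (injury) state. The package is aimed at
epigenomics analysts who want the full analysis chain as tested, reusable
functions, exercised end to end on a bundled synthetic-data generator with
known ground truth.

## What it computes

**Region-summative methylation and the Hyper statistic.** Per gene region
(whole gene, 2 kb TSS-centered promoter, 1–5 kb upstream block, exons,
introns, CpG islands/shores/shelves), methylated and unmethylated cytosine
counts are summed over CpGs and samples, ml = ΣC / Σ(C+T), and compartments
are compared by

&nbsp;&nbsp;&nbsp;&nbsp;Hyper = log2((ml_GLOM + β) / (ml_TI + β)),&nbsp;&nbsp;β = 0.001,

positive when the glomerulus is hypermethylated, with a Welch t-test across
per-sample region levels (BH or Bonferroni correction). Methylation dips —
runs of ml ≤ 0.4 spanning ≥ 50 bp — mark candidate regulatory DNA.

**Chromatin states and the Gisch filter.** Open-chromatin anchors are
classified from overlapping mark peaks: H3K4me3⁺ H3K27ac⁺ in a promoter →
active promoter; H3K4me1⁺ H3K27ac⁺ H3K4me3⁻ outside promoters → predicted
enhancer; otherwise H3K27me3⁺ → repressed. The Gisch filter calls a gene
region a peak (dip) when its per-base signal AUC exceeds (falls below) the
whole-gene average.

**Cross-technology agreement.** Each gene's region units are coded
peak/absent per technology and compared by Cohen's kappa (CK; 1 = perfect
agreement, −1 = perfect disagreement), summarized as the across-gene average
G_T; genome-wide co-occurrence over 1 kb bins is tested with two-sided
Fisher's exact tests.

**Adaptive cell states.** Wilcoxon DE genes (Bonferroni p < 0.05, > 2%
expressing cells, optional |log2FC| > 0.25), logistic-regression DA peaks
(1-df LR test, Bonferroni p < 0.05, |log2FC| > 0 on binarized
accessibility), "new peaks" whose comparator state has < 2% accessible
nuclei, per-gene summative open chromatin within 5 kb of the TSS, and
marker-signature deconvolution (top 10% DEGs with histone promoter peaks,
≥ 20 markers per retained type; constrained least squares).

**Best-fit methylation–expression model.** Per category a univariate
regression of expression log2FC on Hyper; per gene the
negative-correlation category minimizing the standardized residual; overall
fit reported as the concordance index C.

## Worked example

```bash
python analysis/01_simulate.py --seed 1 --out results/data
python analysis/02_methylation.py --seed 1 --out results
python analysis/05_cellstate.py --seed 1 --out results
python analysis/06_expression_model.py --seed 1 --out results
```

prints, among other things:

```
wrote 50 genes, 18729 CpGs, 60 peaks, 65 planted dips to results/data
65 TI dips called; exact match to planted truth: True
DE: 30 significant genes; 20/20 planted adaptive markers recovered
DA: 36 peaks; 12 new peaks (12/12 planted recovered)
deconvolution: {'adaptive': 0.317, 'other': 0.093, 'reference': 0.59} planted: {'reference': 0.6, 'adaptive': 0.3, 'other': 0.1}
overall C = 0.873; planted-category recovery 94.0%
```

The dip caller reproduces every planted low-methylation region exactly; all
20 planted adaptive marker genes are recovered with no false positives; all
12 planted new peaks are found; the mixture estimate is within 0.02 of the
planted proportions; and the best-fit model assigns 94% of genes their true
causal methylation region. The same pipeline runs as one command via
`epichrom run --seed 1 --out results/` or `run_pipeline(PipelineConfig(seed=1))`.

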