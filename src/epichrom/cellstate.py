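"""Reference-vs-adaptive cell-state analysis on single-nucleus matrices:
pseudobulk aggregation, Wilcoxon differential expression, logistic-
regression differential accessibility (DA), "new peak" detection (DA peaks
whose comparator cell state has <2% accessible nuclei), per-gene summative
open-chromatin AUC around the TSS, and marker-signature deconvolution of
bulk profiles by constrained least squares.

A cell "possesses open chromatin" at a peak when its count is > 0; all
accessibility statistics work on that binarized predicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, stats

from .genome import GeneModel, GenomicInterval

__all__ = [
    "CellByFeatureMatrix",
    "DAResult",
    "SignatureMatrix",
    "pseudobulk",
    "de_genes_wilcoxon",
    "da_peaks_lr",
    "find_new_peaks",
    "gene_open_chromatin_auc",
    "build_signature",
    "deconvolve",
    "FC_PSEUDOCOUNT",
]

FC_PSEUDOCOUNT = 0.001  # epsilon in fold-change ratios, DE and DA alike


@dataclass
class CellByFeatureMatrix:
    """Sparse nonnegative counts, features (peaks or genes) x cells, with a
    cell-type label per cell."""

    matrix: sp.spmatrix
    feature_ids: list[str]
    barcodes: list[str]
    labels: np.ndarray
    feature_intervals: list[GenomicInterval] | None = None

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.feature_ids), len(self.barcodes)):
            raise ValueError("matrix shape disagrees with feature/barcode lists")
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.barcodes):
            raise ValueError("labels must cover all cells")
        if self.feature_intervals is not None and len(self.feature_intervals) != len(
            self.feature_ids
        ):
            raise ValueError("feature_intervals misaligned")
        if (self.matrix.data < 0).any():
            raise ValueError("negative counts")

    def cells_of(self, cell_type: str) -> np.ndarray:
        return np.flatnonzero(self.labels == cell_type)

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.labels.tolist()))


def pseudobulk(
    mat: CellByFeatureMatrix, cell_types: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-type summed counts and accessible/expressing-cell fractions.

    fraction = cells of the type with count > 0, divided by cells of the
    type. Every requested type must have >= 1 cell; cells with empty labels
    are rejected.
    """
    if (mat.labels == "").any():
        raise ValueError("unlabeled cells present")
    types = cell_types if cell_types is not None else mat.cell_types
    sums, fracs = {}, {}
    binary = mat.matrix.copy()
    binary.data = (binary.data > 0).astype(float)
    for t in types:
        idx = mat.cells_of(t)
        if len(idx) == 0:
            raise ValueError(f"cell type {t!r} has no cells")
        sums[t] = np.asarray(mat.matrix[:, idx].sum(axis=1)).ravel()
        fracs[t] = np.asarray(binary[:, idx].sum(axis=1)).ravel() / len(idx)
    index = pd.Index(mat.feature_ids, name="feature")
    return pd.DataFrame(sums, index=index), pd.DataFrame(fracs, index=index)


def _lognormalize(counts: sp.spmatrix, scale: float = 1e4) -> sp.csr_matrix:
    """Library-size normalization to ``scale`` counts per cell, then log1p."""
    counts = sp.csc_matrix(counts, dtype=float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    totals[totals == 0] = 1.0
    norm = counts.multiply(scale / totals).tocsr()
    norm.data = np.log1p(norm.data)
    return norm


def de_genes_wilcoxon(
    mat: CellByFeatureMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    min_pct: float = 0.02,
    min_abs_log2fc: float | None = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE between two cell groups on
    log-normalized counts, Bonferroni-corrected over tested genes.

    A gene is tested when expressed (count > 0) in more than ``min_pct`` of
    cells in at least one group. log2FC = log2((mean_a + eps)/(mean_b +
    eps)) on size-normalized counts, so swapping the groups negates it.
    Significance requires Bonferroni p < alpha, plus |log2FC| >
    ``min_abs_log2fc`` when given.
    """
    ia, ib = mat.cells_of(group_a), mat.cells_of(group_b)
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("need >= 3 cells per group")
    norm = _lognormalize(mat.matrix)
    a = norm[:, ia]
    b = norm[:, ib]
    pct_a = np.asarray((a > 0).sum(axis=1)).ravel() / len(ia)
    pct_b = np.asarray((b > 0).sum(axis=1)).ravel() / len(ib)
    tested = (pct_a > min_pct) | (pct_b > min_pct)
    idx = np.flatnonzero(tested)
    if len(idx) == 0:
        return pd.DataFrame(
            columns=["gene", "p", "p_bonferroni", "avg_log2FC", "pct_a", "pct_b", "significant"]
        )
    a_d = np.asarray(a[idx].todense())
    b_d = np.asarray(b[idx].todense())
    res = stats.mannwhitneyu(a_d, b_d, axis=1, alternative="two-sided", method="asymptotic")
    p = np.atleast_1d(res.pvalue)
    # fold change on the size-normalized (pre-log) scale
    mean_a = np.expm1(a_d).mean(axis=1)
    mean_b = np.expm1(b_d).mean(axis=1)
    log2fc = np.log2((mean_a + FC_PSEUDOCOUNT) / (mean_b + FC_PSEUDOCOUNT))
    p_bonf = np.minimum(p * len(idx), 1.0)
    sig = p_bonf < alpha
    if min_abs_log2fc is not None:
        sig &= np.abs(log2fc) > min_abs_log2fc
    return pd.DataFrame(
        {
            "gene": [mat.feature_ids[i] for i in idx],
            "p": p,
            "p_bonferroni": p_bonf,
            "avg_log2FC": log2fc,
            "pct_a": pct_a[idx],
            "pct_b": pct_b[idx],
            "significant": sig,
        }
    ).set_index("gene")


@dataclass
class DAResult:
    peak: str
    interval: GenomicInterval | None
    frac_a: float
    frac_b: float
    avg_log2fc: float
    p: float
    p_bonferroni: float
    is_da: bool
    is_new_peak: bool = False
    new_peak_owner: str | None = None


def _lr_statistic(k_a: np.ndarray, n_a: int, k_b: np.ndarray, n_b: int) -> np.ndarray:
    """Likelihood-ratio statistic (1 df) for logistic regression of group
    on binary accessibility versus the intercept-only null.

    With one binary covariate the fitted model is saturated on the 2x2
    table, so the statistic reduces to the G-statistic
    2 * sum obs * ln(obs * N / (row * col)); statsmodels' Logit agrees to
    numerical precision (checked in the test suite).
    """
    n = n_a + n_b
    cells = np.stack(
        [k_a, n_a - k_a, k_b, n_b - k_b], axis=0
    ).astype(float)  # (4, n_peaks)
    row = np.stack([k_a + k_b, n - k_a - k_b], axis=0).astype(float)
    col = np.array([n_a, n_b], dtype=float)
    expected = np.stack(
        [
            row[0] * col[0] / n,
            row[1] * col[0] / n,
            row[0] * col[1] / n,
            row[1] * col[1] / n,
        ],
        axis=0,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = cells * np.log(cells / expected)
    terms[~np.isfinite(terms)] = 0.0  # 0 * log 0 = 0
    return 2.0 * terms.sum(axis=0)


def da_peaks_lr(
    mat: CellByFeatureMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> list[DAResult]:
    """Differential accessibility between two cell groups.

    Per peak accessible in >= 1 cell of either group: likelihood-ratio test
    (1 df chi-square) of the group~accessibility logistic regression against
    the intercept-only null, Bonferroni-corrected across tested peaks.
    avg_log2FC = log2((frac_a + eps)/(frac_b + eps)); a peak is DA when the
    corrected p < alpha and |log2FC| > 0. Positive log2FC means greater
    open chromatin in group_a.
    """
    ia, ib = mat.cells_of(group_a), mat.cells_of(group_b)
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("need >= 3 cells per group")
    binary = mat.matrix.copy()
    binary.data = (binary.data > 0).astype(float)
    k_a = np.asarray(binary[:, ia].sum(axis=1)).ravel()
    k_b = np.asarray(binary[:, ib].sum(axis=1)).ravel()
    tested = (k_a + k_b) > 0
    idx = np.flatnonzero(tested)
    lr = _lr_statistic(k_a[idx], len(ia), k_b[idx], len(ib))
    p = stats.chi2.sf(lr, df=1)
    p_bonf = np.minimum(p * len(idx), 1.0)
    frac_a = k_a[idx] / len(ia)
    frac_b = k_b[idx] / len(ib)
    log2fc = np.log2((frac_a + FC_PSEUDOCOUNT) / (frac_b + FC_PSEUDOCOUNT))
    out = []
    for j, i in enumerate(idx):
        is_da = bool(p_bonf[j] < alpha and abs(log2fc[j]) > 0)
        out.append(
            DAResult(
                peak=mat.feature_ids[i],
                interval=mat.feature_intervals[i] if mat.feature_intervals else None,
                frac_a=float(frac_a[j]),
                frac_b=float(frac_b[j]),
                avg_log2fc=float(log2fc[j]),
                p=float(p[j]),
                p_bonferroni=float(p_bonf[j]),
                is_da=is_da,
            )
        )
    return out


def find_new_peaks(
    da_results: list[DAResult],
    group_a: str = "adaptive",
    group_b: str = "reference",
    comparator_fraction_threshold: float = 0.02,
) -> list[DAResult]:
    """Flag "new peaks": DA peaks whose down-group (the comparator cell
    state) has strictly fewer than ``comparator_fraction_threshold`` of
    cells with open chromatin. Ownership is the up-group. Mutates and
    returns the input list."""
    for r in da_results:
        r.is_new_peak = False
        r.new_peak_owner = None
        if not r.is_da:
            continue
        if r.avg_log2fc > 0 and r.frac_b < comparator_fraction_threshold:
            r.is_new_peak = True
            r.new_peak_owner = group_a
        elif r.avg_log2fc < 0 and r.frac_a < comparator_fraction_threshold:
            r.is_new_peak = True
            r.new_peak_owner = group_b
    return da_results


def gene_open_chromatin_auc(
    mat: CellByFeatureMatrix,
    gene: GeneModel,
    window_bp: int = 5000,
    cell_types: list[str] | None = None,
) -> pd.Series:
    """Summative open chromatin for a gene: per cell type, the sum of
    accessible-cell fractions over peaks within ``window_bp`` of the TSS.

    A peak qualifies when fully contained in [tss - window, tss + window],
    or when it overlaps the TSS base itself. Genes with no qualifying peak
    get 0 for every type.
    """
    if mat.feature_intervals is None:
        raise ValueError("peak matrix lacks coordinates")
    tss = gene.tss
    lo, hi = tss - window_bp, tss + window_bp
    qualifying = [
        i
        for i, iv in enumerate(mat.feature_intervals)
        if iv.chrom == gene.chrom
        and ((iv.start >= lo and iv.end <= hi) or iv.contains_point(tss))
    ]
    types = cell_types if cell_types is not None else mat.cell_types
    _, fracs = pseudobulk(mat, types)
    if not qualifying:
        return pd.Series(0.0, index=types, name=gene.gene_id)
    sub = fracs.iloc[qualifying]
    return sub.sum(axis=0).rename(gene.gene_id)


@dataclass
class SignatureMatrix:
    """Marker-gene reference profiles per retained cell type."""

    profiles: pd.DataFrame  # marker genes x retained cell types
    markers: dict[str, list[str]] = field(default_factory=dict)

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)


def build_signature(
    de_tables: dict[str, pd.DataFrame],
    promoter_peak_genes: set[str],
    profiles: pd.DataFrame,
    top_fraction: float = 0.10,
    min_markers: int = 20,
    drop_types: tuple[str, ...] = (),
) -> SignatureMatrix:
    """Marker signature for deconvolution.

    Per cell type: take the top ``top_fraction`` of its marker DEGs (tables
    assumed ranked best-first), keep those with a promoter peak in at least
    one histone mark, and retain the type only when >= ``min_markers``
    survive. ``drop_types`` removes configured types outright. Signature
    values are the per-type pseudobulk ``profiles`` over the union of
    retained markers.
    """
    markers: dict[str, list[str]] = {}
    for ctype, table in de_tables.items():
        if ctype in drop_types:
            continue
        genes = list(table.index)
        top = genes[: int(len(genes) * top_fraction)]
        kept = [g for g in top if g in promoter_peak_genes]
        if len(kept) >= min_markers:
            markers[ctype] = kept
    if not markers:
        raise ValueError("no cell type retains enough markers")
    all_markers = sorted(set(g for ms in markers.values() for g in ms))
    profile = profiles.loc[all_markers, sorted(markers)]
    return SignatureMatrix(profile, markers)


def deconvolve(signature: SignatureMatrix, bulk: pd.Series) -> pd.Series:
    """Mixture proportions of bulk over signature cell types: nonnegative
    least squares, renormalized onto the simplex."""
    missing = signature.profiles.index.difference(bulk.index)
    if len(missing):
        raise ValueError(f"bulk profile missing {len(missing)} signature markers")
    A = signature.profiles.to_numpy(dtype=float)
    y = bulk.loc[signature.profiles.index].to_numpy(dtype=float)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn("rank-deficient signature; solution is minimum-norm")
    coef, _ = optimize.nnls(A, y)
    total = coef.sum()
    if total == 0:
        coef = np.full_like(coef, 1.0 / len(coef))
    else:
        coef = coef / total
    return pd.Series(coef, index=signature.cell_types, name="proportion")
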