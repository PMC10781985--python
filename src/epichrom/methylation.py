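"""WGBS arm: per-CpG count tracks, region-summative methylation levels for
the two microdissected kidney compartments (GLOM = glomeruli, TI =
tubulointerstitium), the Hyper log-ratio statistic, differential testing,
methylation-dip calling, and the per-gene best-fit methylation-expression
model.

Methylation level of a region is count-pooled: sum methylated cytosine
counts (#C) and divide by summed coverage (#C + #T) over all CpGs and all
selected samples — not a mean of per-sample ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomicInterval

__all__ = [
    "CpGMethylationTrack",
    "BestFitResult",
    "filter_cpgs",
    "summative_methylation",
    "hyper",
    "diff_region_methylation",
    "windowed_methylation",
    "call_methyl_dips",
    "concordance_index",
    "best_fit_expression_model",
]

GLOM = "GLOM"
TI = "TI"


@dataclass
class CpGMethylationTrack:
    """Per-CpG methylated (#C) and unmethylated (#T) counts, per sample and
    compartment.

    ``numC[comp]`` and ``numT[comp]`` are (n_sites, n_samples) integer
    arrays aligned with ``chrom``/``pos``; coverage is their sum.
    """

    chrom: np.ndarray
    pos: np.ndarray
    numC: dict[str, np.ndarray]
    numT: dict[str, np.ndarray]
    samples: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.pos)
        for comp in self.numC:
            if self.numC[comp].shape[0] != n or self.numT[comp].shape[0] != n:
                raise ValueError("count arrays misaligned with site list")
            if (self.numC[comp] < 0).any() or (self.numT[comp] < 0).any():
                raise ValueError("negative counts")
            if comp not in self.samples:
                self.samples[comp] = [
                    f"{comp}_{i+1}" for i in range(self.numC[comp].shape[1])
                ]

    @property
    def compartments(self) -> list[str]:
        return list(self.numC)

    def n_sites(self) -> int:
        return len(self.pos)

    def coverage(self, compartment: str) -> np.ndarray:
        return self.numC[compartment] + self.numT[compartment]

    def site_mask(self, region: GenomicInterval) -> np.ndarray:
        return (
            (self.chrom == region.chrom)
            & (self.pos >= region.start)
            & (self.pos < region.end)
        )

    def subset(self, mask: np.ndarray) -> "CpGMethylationTrack":
        return CpGMethylationTrack(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            numC={c: a[mask] for c, a in self.numC.items()},
            numT={c: a[mask] for c, a in self.numT.items()},
            samples={c: list(s) for c, s in self.samples.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: chrom, pos, sample, compartment, numC, numT."""
        rows = []
        for comp in self.compartments:
            for j, name in enumerate(self.samples[comp]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chrom": self.chrom,
                            "pos": self.pos,
                            "sample": name,
                            "compartment": comp,
                            "numC": self.numC[comp][:, j],
                            "numT": self.numT[comp][:, j],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def filter_cpgs(
    track: CpGMethylationTrack, min_coverage: int = 5
) -> CpGMethylationTrack:
    """Keep CpG sites with coverage strictly greater than ``min_coverage``
    reads in every sample of every compartment."""
    keep = np.ones(track.n_sites(), dtype=bool)
    for comp in track.compartments:
        keep &= (track.coverage(comp) > min_coverage).all(axis=1)
    return track.subset(keep)


def summative_methylation(
    track: CpGMethylationTrack,
    region: GenomicInterval,
    compartment: str,
    sample_indices: np.ndarray | list[int] | None = None,
) -> float:
    """Region methylation level: sum #C / sum (#C + #T) over all CpGs in
    the region and all selected samples. NaN sentinel when the region has
    zero pooled coverage (excluded downstream, never reported as 0)."""
    mask = track.site_mask(region)
    numc = track.numC[compartment][mask]
    numt = track.numT[compartment][mask]
    if sample_indices is not None:
        numc = numc[:, sample_indices]
        numt = numt[:, sample_indices]
    total = numc.sum() + numt.sum()
    if total == 0:
        return math.nan
    return float(numc.sum() / total)


def pooled_mask_ml(
    track: CpGMethylationTrack,
    intervals: list[GenomicInterval],
    compartment: str,
) -> float:
    """Count-pooled methylation over a union of intervals (e.g. all exons
    of one gene), all samples; NaN when nothing is covered."""
    mask = np.zeros(track.n_sites(), dtype=bool)
    for iv in intervals:
        mask |= track.site_mask(iv)
    c = track.numC[compartment][mask].sum()
    t = track.numT[compartment][mask].sum()
    return math.nan if c + t == 0 else float(c / (c + t))


def per_sample_pooled_ml(
    track: CpGMethylationTrack,
    intervals: list[GenomicInterval],
    compartment: str,
) -> np.ndarray:
    """Per-sample count-pooled methylation over a union of intervals."""
    mask = np.zeros(track.n_sites(), dtype=bool)
    for iv in intervals:
        mask |= track.site_mask(iv)
    numc = track.numC[compartment][mask].sum(axis=0).astype(float)
    cov = numc + track.numT[compartment][mask].sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(cov > 0, numc / np.maximum(cov, 1), np.nan)


def per_sample_region_ml(
    track: CpGMethylationTrack, region: GenomicInterval, compartment: str
) -> np.ndarray:
    """Per-sample pooled region methylation (NaN for zero-coverage samples)."""
    mask = track.site_mask(region)
    numc = track.numC[compartment][mask].sum(axis=0).astype(float)
    cov = numc + track.numT[compartment][mask].sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(cov > 0, numc / np.maximum(cov, 1), np.nan)


def hyper(ml_glom: float, ml_ti: float, beta: float = 0.001) -> float:
    """Relative (hyper-)methylation between compartments:
    log2((ml_GLOM + beta) / (ml_TI + beta)).

    Positive values mean greater methylation in the glomerulus; the
    pseudocount beta keeps the ratio finite for fully unmethylated regions.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    for v in (ml_glom, ml_ti):
        if not 0 <= v <= 1:
            raise ValueError("methylation levels must lie in [0, 1]")
    return math.log2((ml_glom + beta) / (ml_ti + beta))


def diff_region_methylation(
    ml_glom: np.ndarray,
    ml_ti: np.ndarray,
    correction: str = "BH",
) -> pd.DataFrame:
    """Welch two-sample t-test per region on per-sample methylation levels.

    ``ml_glom``/``ml_ti`` are (n_regions, n_samples) arrays; NaN samples are
    dropped per region. Regions where both groups are constant with equal
    means get t = 0, p = 1. Correction: 'BH' (Benjamini-Hochberg) or
    'bonferroni', applied across all tested regions.
    """
    if correction not in ("BH", "bonferroni"):
        raise ValueError("correction must be 'BH' or 'bonferroni'")
    ml_glom = np.atleast_2d(np.asarray(ml_glom, dtype=float))
    ml_ti = np.atleast_2d(np.asarray(ml_ti, dtype=float))
    n = ml_glom.shape[0]
    t = np.zeros(n)
    p = np.ones(n)
    for i in range(n):
        a = ml_glom[i][~np.isnan(ml_glom[i])]
        b = ml_ti[i][~np.isnan(ml_ti[i])]
        if len(a) < 2 or len(b) < 2:
            t[i], p[i] = np.nan, np.nan
            continue
        if a.std() == 0 and b.std() == 0:
            if a.mean() == b.mean():
                t[i], p[i] = 0.0, 1.0
            else:
                t[i], p[i] = np.inf * np.sign(a.mean() - b.mean()), 0.0
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        t[i], p[i] = res.statistic, res.pvalue
    tested = ~np.isnan(p)
    p_adj = np.full(n, np.nan)
    if correction == "bonferroni":
        p_adj[tested] = np.minimum(p[tested] * tested.sum(), 1.0)
    else:
        p_adj[tested] = stats.false_discovery_control(p[tested], method="bh")
    return pd.DataFrame({"t_stat": t, "p_value": p, "p_adjusted": p_adj})


def windowed_methylation(
    track: CpGMethylationTrack,
    compartment: str,
    chrom: str,
    chrom_length: int,
    window: int = 10,
) -> np.ndarray:
    """Pooled (all-sample) methylation level per fixed ``window`` bp bin
    along ``chrom``; NaN for bins without covered CpGs."""
    n_bins = -(-chrom_length // window)
    on = track.chrom == chrom
    pos = track.pos[on]
    numc = track.numC[compartment][on].sum(axis=1)
    cov = numc + track.numT[compartment][on].sum(axis=1)
    bins = pos // window
    c_sum = np.bincount(bins, weights=numc, minlength=n_bins)
    cov_sum = np.bincount(bins, weights=cov, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        return np.where(cov_sum > 0, c_sum / np.maximum(cov_sum, 1), np.nan)


def call_methyl_dips(
    ml_bins: np.ndarray,
    chrom: str,
    window: int = 10,
    max_ml: float = 0.4,
    min_len_bp: int = 50,
) -> list[GenomicInterval]:
    """Methylation dips: maximal runs of consecutive bins with methylation
    level <= ``max_ml``, reported when the run spans >= ``min_len_bp``.

    ``ml_bins`` is the output of :func:`windowed_methylation`; NaN bins
    (no covered CpGs) break runs. Adjacent qualifying bins merge into one
    maximal dip, so reported dips never touch or overlap.
    """
    ml = np.asarray(ml_bins, dtype=float)
    low = np.isfinite(ml) & (ml <= max_ml)
    out: list[GenomicInterval] = []
    i = 0
    n = len(low)
    while i < n:
        if low[i]:
            j = i
            while j < n and low[j]:
                j += 1
            if (j - i) * window >= min_len_bp:
                out.append(GenomicInterval(chrom, i * window, j * window))
            i = j
        else:
            i += 1
    return out


def concordance_index(predicted: np.ndarray, observed: np.ndarray) -> float:
    """C-statistic: probability over unordered pairs that predicted and
    observed values are concordantly ordered; pairs tied in either variable
    count 0.5. 1 = perfect concordance, 0 = perfect discordance, 0.5 =
    no association (all-tied observed returns 0.5)."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if len(pred) != len(obs) or len(pred) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    dp = np.sign(pred[:, None] - pred[None, :])
    do = np.sign(obs[:, None] - obs[None, :])
    iu = np.triu_indices(len(pred), k=1)
    prod = dp[iu] * do[iu]
    score = (prod > 0).sum() + 0.5 * (prod == 0).sum()
    return float(score / len(prod))


@dataclass
class BestFitResult:
    """Per-gene best-fit category and overall fit of the
    methylation-expression model."""

    category_r: dict[str, float]
    regressions: dict[str, tuple[float, float, float]]  # slope, intercept, resid sd
    selected: pd.Series  # gene -> category
    predicted: pd.Series  # gene -> predicted expression log2FC
    concordance: float

    def category_counts(self) -> pd.Series:
        return self.selected.value_counts()


def best_fit_expression_model(
    methylation: pd.DataFrame, expression: pd.Series
) -> BestFitResult:
    """Best-fit model of expression on region methylation.

    ``methylation``: genes x region categories, differential methylation
    (Hyper) per category; ``expression``: differential expression (log2FC)
    per gene. Per category a univariate regression of expression on
    methylation is fit across genes and its Pearson r recorded. Categories
    with negative genome-wide r form the candidate set; each gene takes the
    candidate minimizing its absolute standardized residual (genes with no
    finite candidate value fall back to the most negative-r category). The
    overall fit is the concordance index between the combined per-gene
    predictions and observed expression.
    """
    if methylation.shape[1] < 2:
        raise ValueError("need at least two region categories")
    genes = methylation.index
    expression = expression.loc[genes]
    if len(genes) < 10:
        raise ValueError("need at least 10 genes")

    category_r: dict[str, float] = {}
    regressions: dict[str, tuple[float, float, float]] = {}
    for cat in methylation.columns:
        x = methylation[cat].to_numpy(dtype=float)
        y = expression.to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0:
            continue  # constant or empty column: excluded
        res = stats.linregress(x[ok], y[ok])
        resid = y[ok] - (res.intercept + res.slope * x[ok])
        sd = resid.std(ddof=2) if len(resid) > 2 else resid.std()
        category_r[cat] = float(res.rvalue)
        regressions[cat] = (float(res.slope), float(res.intercept), float(max(sd, 1e-12)))

    if not category_r:
        raise ValueError("no usable category columns")
    negative = [c for c, r in category_r.items() if r < 0]
    fallback = min(category_r, key=category_r.get)
    candidates = negative if negative else [fallback]

    selected = {}
    predicted = {}
    for g in genes:
        y = float(expression.loc[g])
        best_cat, best_z = None, np.inf
        for cat in candidates:
            x = methylation.at[g, cat]
            if not np.isfinite(x):
                continue
            slope, intercept, sd = regressions[cat]
            z = abs(y - (intercept + slope * x)) / sd
            if z < best_z:
                best_cat, best_z = cat, z
        if best_cat is None:
            best_cat = fallback
        slope, intercept, _ = regressions[best_cat]
        x = methylation.at[g, best_cat]
        selected[g] = best_cat
        predicted[g] = intercept + slope * x if np.isfinite(x) else np.nan
    sel = pd.Series(selected, name="selected_category")
    pred = pd.Series(predicted, name="predicted")
    ok = pred.notna()
    c = concordance_index(pred[ok].to_numpy(), expression[ok].to_numpy())
    return BestFitResult(category_r, regressions, sel, pred, c)
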