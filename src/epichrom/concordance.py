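"""Cross-technology agreement: code each gene's region units as binary
peak/dip calls per technology, quantify pairwise agreement with Cohen's
kappa, summarize across genes, and test genome-wide co-occurrence of
features with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionCoding",
    "KappaResult",
    "code_gene_regions",
    "cohens_kappa",
    "fisher_association",
    "kappa_summary",
    "KAPPA_BANDS",
]

KAPPA_BANDS = ("<0", "[0,0.2)", "[0.2,0.4)", "[0.4,0.6)", "[0.6,0.8)", "[0.8,1]")


@dataclass
class RegionCoding:
    """Binary label vectors (1 = peak/dip, 0 = absent) per technology over
    one gene's position-ordered region units."""

    gene_id: str
    unit_keys: list[tuple]  # (chrom, start, end, category), position-sorted
    labels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.unit_keys)
        for tech, vec in self.labels.items():
            vec = np.asarray(vec, dtype=int)
            if len(vec) != n or not np.isin(vec, (0, 1)).all():
                raise ValueError(f"bad label vector for {tech}")
            self.labels[tech] = vec


@dataclass
class KappaResult:
    gene_id: str
    tech_a: str
    tech_b: str
    kappa: float
    n_units: int
    table: np.ndarray  # 2x2 contingency, rows = a in {0,1}, cols = b
    degenerate: bool = False


def code_gene_regions(
    gene_id: str,
    units: list[tuple],
    calls: dict[str, dict[int, str]],
) -> RegionCoding:
    """Assemble a RegionCoding from per-technology Gisch/dip calls.

    ``units``: (chrom, start, end, category) tuples for the gene;
    ``calls``: technology -> {unit index -> 'peak'/'dip'/'absent'}. Units
    are sorted by genomic position and all technologies are coded over the
    identical sorted unit list.
    """
    if len(units) < 2:
        raise ValueError("gene needs >= 2 region units to be codable")
    order = sorted(range(len(units)), key=lambda i: units[i])
    sorted_units = [units[i] for i in order]
    labels = {}
    for tech, call in calls.items():
        vec = np.array(
            [1 if call.get(i, "absent") in ("peak", "dip") else 0 for i in order],
            dtype=int,
        )
        labels[tech] = vec
    return RegionCoding(gene_id, sorted_units, labels)


def cohens_kappa(labels_a: np.ndarray, labels_b: np.ndarray) -> tuple[float, bool]:
    """Cohen's kappa for two binary vectors: (p_o - p_e) / (1 - p_e), with
    observed agreement p_o and chance agreement p_e from the marginals.

    Degenerate case p_e = 1 (both vectors constant): identical constants
    give kappa 1, differing constants -1 (limit convention); the second
    return value flags it. Range [-1, 1]; 1 only for identical vectors.
    """
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need equal-length vectors, n >= 2")
    p_o = float((a == b).mean())
    p_a1, p_b1 = a.mean(), b.mean()
    if p_a1 in (0.0, 1.0) and p_b1 in (0.0, 1.0):
        # both vectors constant: chance agreement is undefined at the
        # limit; identical constants -> 1, opposite constants -> -1
        return (1.0, True) if p_o == 1.0 else (-1.0, True)
    p_e = p_a1 * p_b1 + (1 - p_a1) * (1 - p_b1)
    return float((p_o - p_e) / (1 - p_e)), False


def kappa_for_gene(coding: RegionCoding, tech_a: str, tech_b: str) -> KappaResult:
    a, b = coding.labels[tech_a], coding.labels[tech_b]
    k, degenerate = cohens_kappa(a, b)
    table = np.array(
        [
            [int(((a == 0) & (b == 0)).sum()), int(((a == 0) & (b == 1)).sum())],
            [int(((a == 1) & (b == 0)).sum()), int(((a == 1) & (b == 1)).sum())],
        ]
    )
    return KappaResult(coding.gene_id, tech_a, tech_b, k, len(a), table, degenerate)


def fisher_association(
    flags_a: np.ndarray, flags_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Fisher exact test of co-occurrence between two binary flag
    vectors over genome units.

    Returns (odds_ratio, p). Degenerate margins (a vector all 0 or all 1)
    give p = 1 and OR = NaN. A zero cell yields the Haldane-corrected OR
    (0.5 added to every cell) for reporting; the p-value always comes from
    the uncorrected table (inf OR is reported as inf before correction only
    when no cell is zero, which cannot happen — hence Haldane).
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    if a.all() or (~a).all() or b.all() or (~b).all():
        return float("nan"), 1.0
    table = np.array(
        [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
    )
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    if (table == 0).any():
        t = table + 0.5
        orat = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    else:
        orat = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
    return orat, p


def kappa_summary(results: list[KappaResult]) -> tuple[float, pd.Series]:
    """Unweighted mean kappa across genes (the G_T summary) plus counts per
    agreement band."""
    if not results:
        raise ValueError("no kappa results")
    ks = np.array([r.kappa for r in results])
    g_t = float(ks.mean())
    edges = [-np.inf, 0.0, 0.2, 0.4, 0.6, 0.8, np.inf]
    counts = pd.Series(0, index=list(KAPPA_BANDS))
    idx = np.searchsorted(edges, ks, side="right") - 1
    # kappa == 1 lands in the top band
    idx = np.clip(idx, 0, len(KAPPA_BANDS) - 1)
    for i in idx:
        counts.iloc[i] += 1
    return g_t, counts
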