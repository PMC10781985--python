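"""Histone-mark / open-chromatin arm: per-region signal AUC, the per-gene
AUC-threshold ("Gisch") peak and dip filter, rule-based chromatin-state
classification from mark combinations, dip-overlap filtering of peaks, and
upset-style intersection counts.

States follow the standard histone-code reading: H3K4me3 + H3K27ac at a
promoter marks an active promoter, H3K4me1 + H3K27ac away from promoters
(without H3K4me3) a predicted enhancer, H3K27me3 a repressed region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import GeneModel, GenomicInterval, RegionEntry, merge_intervals, overlap_intervals

__all__ = [
    "SignalTrack",
    "MarkPeakSet",
    "StateCall",
    "region_auc",
    "gisch_filter",
    "classify_chromatin_state",
    "annotate_states",
    "filter_peaks_by_dips",
    "upset_counts",
]

MARKS = ("H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3")


@dataclass
class SignalTrack:
    """Nonnegative per-base coverage, one array per chromosome."""

    mark: str
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for c, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if (v < 0).any():
                raise ValueError(f"negative signal on {c}")
            self.values[c] = v


@dataclass
class MarkPeakSet:
    """Peak intervals for one mark; ``reduce`` gives the sorted merged set."""

    mark: str
    peaks: list[GenomicInterval] = field(default_factory=list)

    def reduce(self) -> "MarkPeakSet":
        return MarkPeakSet(self.mark, merge_intervals(self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class StateCall:
    peak: GenomicInterval
    marks_present: frozenset
    in_promoter: bool
    in_gene_body: bool
    has_dip: bool
    state: str


def region_auc(
    track: SignalTrack, region: GenomicInterval, normalize: bool = True
) -> float:
    """Area under the signal over a region: per-base sum, optionally divided
    by region length (per-base density)."""
    arr = track.values[region.chrom]
    total = float(arr[region.start : region.end].sum())
    return total / len(region) if normalize else total


def gisch_filter(
    track: SignalTrack,
    gene: GeneModel,
    regions: Sequence[RegionEntry],
    mode: str = "peak",
    normalize: bool = True,
) -> dict[int, str]:
    """Per-gene AUC-threshold filter.

    Each region's AUC (per-base density by default) is compared with the
    whole-gene AUC: in ``peak`` mode a region is a peak iff its AUC is
    strictly greater than the gene's; in ``dip`` mode iff strictly less
    (the methylation convention). Ties are 'absent'. Returns
    {region index -> 'peak'|'dip'|'absent'}.
    """
    if mode not in ("peak", "dip"):
        raise ValueError("mode must be 'peak' or 'dip'")
    gene_auc = region_auc(track, gene.span, normalize=normalize)
    out: dict[int, str] = {}
    for i, entry in enumerate(regions):
        auc = region_auc(track, entry.interval, normalize=normalize)
        if mode == "peak":
            out[i] = "peak" if auc > gene_auc else "absent"
        else:
            out[i] = "dip" if auc < gene_auc else "absent"
    return out


def classify_chromatin_state(
    marks_present: Iterable[str],
    in_promoter: bool,
    in_gene_body: bool = False,
    strict_enhancer: bool = False,
) -> str:
    """Rule-based chromatin state from mark presence and location.

    Rules, in order: (1) H3K4me3+ and H3K27ac+ in a promoter -> active
    promoter (H3K4me1 free either way); (2) H3K4me1+ and H3K27ac+ without
    H3K4me3 outside promoters -> predicted enhancer (``strict_enhancer``
    additionally requires an extragenic location); (3) otherwise H3K27me3+
    -> repressed; else unclassified. Pure function of its arguments.
    """
    marks = frozenset(marks_present)
    if "H3K4me3" in marks and "H3K27ac" in marks and in_promoter:
        return "active_promoter"
    if (
        "H3K4me1" in marks
        and "H3K27ac" in marks
        and "H3K4me3" not in marks
        and not in_promoter
        and not (strict_enhancer and in_gene_body)
    ):
        return "predicted_enhancer"
    if "H3K27me3" in marks:
        return "repressed"
    return "unclassified"


def annotate_states(
    anchor_peaks: Sequence[GenomicInterval],
    mark_peaks: Mapping[str, Sequence[GenomicInterval]],
    promoters: Sequence[GenomicInterval],
    gene_bodies: Sequence[GenomicInterval] = (),
    dips: Sequence[GenomicInterval] = (),
    strict_enhancer: bool = False,
) -> list[StateCall]:
    """Classify each anchor (open-chromatin) peak by which histone-mark peak
    sets overlap it (>= 1 bp) and whether it lies in a promoter/gene body."""

    def hit_flags(features: Sequence[GenomicInterval]) -> np.ndarray:
        flags = np.zeros(len(anchor_peaks), dtype=bool)
        for i, _ in overlap_intervals(list(anchor_peaks), list(features)):
            flags[i] = True
        return flags

    mark_hits = {m: hit_flags(list(ps)) for m, ps in mark_peaks.items()}
    prom_hits = hit_flags(list(promoters))
    body_hits = hit_flags(list(gene_bodies))
    dip_hits = hit_flags(list(dips))
    calls = []
    for i, pk in enumerate(anchor_peaks):
        present = frozenset(m for m, h in mark_hits.items() if h[i])
        state = classify_chromatin_state(
            present, bool(prom_hits[i]), bool(body_hits[i]), strict_enhancer
        )
        calls.append(
            StateCall(pk, present, bool(prom_hits[i]), bool(body_hits[i]), bool(dip_hits[i]), state)
        )
    return calls


def filter_peaks_by_dips(
    peaks: MarkPeakSet, dips: Sequence[GenomicInterval]
) -> MarkPeakSet:
    """Peaks overlapping at least one methylation dip by >= 1 bp, input
    order preserved."""
    hit = set(i for i, _ in overlap_intervals(peaks.peaks, list(dips)))
    return MarkPeakSet(peaks.mark, [p for i, p in enumerate(peaks.peaks) if i in hit])


def upset_counts(
    anchor: MarkPeakSet, feature_sets: Mapping[str, Sequence[GenomicInterval]]
) -> dict[frozenset, int]:
    """Upset-style intersection tally: each anchor peak is assigned the
    exact combination of feature sets it overlaps; counts over combinations
    sum to the number of anchor peaks."""
    if not feature_sets:
        raise ValueError("need at least one feature set")
    membership: list[set] = [set() for _ in anchor.peaks]
    for name, feats in feature_sets.items():
        for i, _ in overlap_intervals(anchor.peaks, list(feats)):
            membership[i].add(name)
    counts: dict[frozenset, int] = {}
    for m in membership:
        key = frozenset(m)
        counts[key] = counts.get(key, 0) + 1
    return counts


def all_combination_counts(
    anchor: MarkPeakSet, feature_sets: Mapping[str, Sequence[GenomicInterval]]
) -> dict[frozenset, int]:
    """As :func:`upset_counts` but listing every 2^k combination, zeros
    included — convenient for plotting tables."""
    counts = upset_counts(anchor, feature_sets)
    names = list(feature_sets)
    full = {}
    for r in range(len(names) + 1):
        for combo in combinations(names, r):
            key = frozenset(combo)
            full[key] = counts.get(key, 0)
    return full
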