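"""Synthetic multi-modal kidney-epigenome generator.

Emits a miniature two-compartment (GLOM/TI) dataset with known ground
truth: a toy genome of non-overlapping genes with exon/intron structure
and gene-body CpG islands; per-CpG bisulfite counts with planted
methylation dips and compartment-differential "causal" regions; histone
mark and ATAC peak sets consistent with planted chromatin states; a
three-cell-type (reference / adaptive / other) binarized peak-by-cell
matrix with planted differential-accessibility classes and "new peaks";
a gene-by-cell expression matrix with planted DE genes; and a bulk
expression table whose differential expression is anti-correlated with
the methylation of each gene's causal region.

Every stage draws from its own seeded stream (``seed`` plus a fixed
per-stage offset), so outputs are reproducible per stage and overall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cellstate import CellByFeatureMatrix
from .chromatin import MarkPeakSet, SignalTrack
from .genome import GeneModel, GenomicInterval
from .methylation import CpGMethylationTrack, GLOM, TI, hyper

__all__ = [
    "SimulationConfig",
    "TruthBundle",
    "SyntheticDataset",
    "generate_genome",
    "simulate_methylation",
    "simulate_mark_tracks",
    "simulate_cells",
    "simulate_expression",
    "simulate_bulk_mixture",
    "simulate_all",
]

CELL_TYPES = ("reference", "adaptive", "other")
CAUSAL_CATEGORIES = ("promoter", "cpg_island", "exon", "intron")

# per-stage offsets for independent seeded streams
_STREAMS = {"genome": 1, "methylation": 2, "marks": 3, "cells": 4, "expression": 5, "bulk": 6}


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic dataset (miniature scale chosen so
    the full pipeline runs in about a minute on one CPU)."""

    n_chroms: int = 2
    chrom_length_bp: int = 1_000_000
    n_genes: int = 50
    n_samples_per_compartment: int = 4
    n_cells_per_type: int = 300
    high_ml: float = 0.85
    low_ml: float = 0.15
    coverage_mean: float = 30.0
    dropout: float = 0.1
    de_log2fc: float = 2.0
    n_de_genes: int = 20  # adaptive-state marker genes
    n_markers_secondary: int = 10  # marker genes each for reference and other
    n_background_genes: int = 450  # non-genomic transcriptome filler, never DE
    acc_null: float = 0.30
    acc_high: float = 0.60
    acc_low: float = 0.15
    acc_other: float = 0.25
    expression_slope: float = 1.0
    expression_noise: float = 0.25  # noise sd as a fraction of signal sd
    mixture: tuple = (0.6, 0.3, 0.1)  # reference, adaptive, other
    active_frac: float = 0.6
    repressed_frac: float = 0.2
    enhancer_frac: float = 0.5
    h3k4me1_at_promoter_p: float = 0.5
    peak_height: float = 10.0
    noise_floor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.low_ml < self.high_ml <= 1):
            raise ValueError("require 0 <= low_ml < high_ml <= 1")
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stage]])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mixture"] = list(self.mixture)
        return d


@dataclass
class _GeneLayout:
    """Generator-internal geometry of one gene: the CpG-dense promoter
    block (grid-aligned), gene-body CpG island, enhancer slot, and the
    tagged CpG positions used for methylation assignment."""

    dense_block: GenomicInterval
    island: GenomicInterval
    enhancer: GenomicInterval | None
    cpg_by_tag: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class TruthBundle:
    """Planted ground truth for recovery tests."""

    gene_states: dict[str, str] = field(default_factory=dict)
    region_states: dict[GenomicInterval, str] = field(default_factory=dict)
    planted_dips: list[GenomicInterval] = field(default_factory=list)
    causal_region: dict[str, str] = field(default_factory=dict)
    expressed_compartment: dict[str, str] = field(default_factory=dict)
    da_truth: dict[str, str] = field(default_factory=dict)
    new_peak_truth: dict[str, str | None] = field(default_factory=dict)
    de_truth: dict[str, str] = field(default_factory=dict)
    mixture: dict[str, float] = field(default_factory=dict)
    layouts: dict[str, _GeneLayout] = field(default_factory=dict)

    def validate(self) -> None:
        if self.mixture and abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ValueError("mixture must sum to 1")
        dips = sorted(self.planted_dips)
        for a, b in zip(dips, dips[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError("planted dips must be disjoint")


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def generate_genome(
    config: SimulationConfig,
) -> tuple[list[GeneModel], list[GenomicInterval], TruthBundle]:
    """Lay out non-overlapping genes on the toy genome and assign the
    planted chromatin state, expressed compartment, and causal methylation
    category of each gene.

    Genes occupy evenly spaced slots; each has 2-4 exons. The first exon
    spans the downstream promoter half and the first intron is >= 2 kb,
    holding a 150 bp gene-body CpG island clear of the promoter window; a
    grid-aligned 300 bp CpG-dense block sits immediately upstream of the
    TSS; half the slots carry a 200 bp intergenic enhancer ~6 kb from any
    TSS. Raises when slots are too small to pack a gene.
    """
    rng = config.rng("genome")
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    islands: list[GenomicInterval] = []
    truth = TruthBundle()
    truth.mixture = dict(zip(CELL_TYPES, config.mixture))

    # stratified state assignment with exact counts, so downstream marker
    # selection can rely on the number of active genes
    n_active = round(config.active_frac * config.n_genes)
    n_repressed = round(config.repressed_frac * config.n_genes)
    states = np.array(
        ["active_promoter"] * n_active
        + ["repressed"] * n_repressed
        + ["background"] * (config.n_genes - n_active - n_repressed),
        dtype=object,
    )
    states = rng.permutation(states)
    causal = rng.choice(CAUSAL_CATEGORIES, size=config.n_genes)
    # balanced compartment assignment stratified by causal category, so
    # differential directions are sign-symmetric within each category
    compartments = np.empty(config.n_genes, dtype=object)
    for cat in CAUSAL_CATEGORIES:
        idx = np.flatnonzero(causal == cat)
        half = [GLOM, TI] * (len(idx) // 2 + 1)
        compartments[idx] = rng.permutation(half[: len(idx)])

    g_index = 0
    for ci, n_on_chrom in enumerate(per_chrom):
        if n_on_chrom == 0:
            continue
        chrom = _chrom_name(ci)
        slot_w = (config.chrom_length_bp // n_on_chrom) // 10 * 10
        if slot_w < 26000:
            raise ValueError(
                f"infeasible packing: slot width {slot_w} bp < 26 kb on {chrom}"
            )
        for s in range(n_on_chrom):
            slot = s * slot_w
            gene_id = f"gene_{g_index:04d}"
            strand = str(rng.choice(["+", "-"]))
            n_exons = int(rng.integers(2, 5))
            exon_lens = rng.integers(30, 61, size=n_exons) * 10
            # first exon covers the downstream promoter half, so introns
            # start outside the 2 kb promoter window
            exon_lens[0] = int(rng.integers(100, 121)) * 10
            intron_lens = rng.integers(80, 201, size=n_exons - 1) * 10
            intron_lens[0] = max(intron_lens[0], 2000)
            L = int(exon_lens.sum() + intron_lens.sum())
            gstart = slot + 8000
            span = GenomicInterval(chrom, gstart, gstart + L, strand)

            # 5'-relative exon offsets -> genomic intervals
            offs = []
            o = 0
            for k in range(n_exons):
                offs.append((o, o + int(exon_lens[k])))
                o += int(exon_lens[k])
                if k < n_exons - 1:
                    o += int(intron_lens[k])
            if strand == "+":
                exons = [GenomicInterval(chrom, gstart + a, gstart + b, strand) for a, b in offs]
            else:
                exons = sorted(
                    GenomicInterval(chrom, gstart + L - b, gstart + L - a, strand)
                    for a, b in offs
                )
            gene = GeneModel(gene_id, gene_id.upper(), strand, span, exons)
            genes.append(gene)

            # island: 150 bp inside intron 1 (5'-relative [e1+600, e1+750)),
            # clear of the promoter window since e1 >= 1000
            e1 = int(exon_lens[0])
            if strand == "+":
                isl = GenomicInterval(chrom, gstart + e1 + 600, gstart + e1 + 750)
            else:
                isl = GenomicInterval(chrom, gstart + L - e1 - 750, gstart + L - e1 - 600)
            islands.append(isl)

            # grid-aligned CpG-dense promoter block just upstream of the
            # TSS (keeps dense CpGs out of exon 1)
            t0 = gene.tss if strand == "+" else gene.tss + 1
            if strand == "+":
                dense = GenomicInterval(chrom, t0 - 300, t0)
            else:
                dense = GenomicInterval(chrom, t0, t0 + 300)

            enhancer = None
            if rng.random() < config.enhancer_frac:
                enhancer = GenomicInterval(chrom, slot + 2000, slot + 2200)

            truth.gene_states[gene_id] = str(states[g_index])
            truth.expressed_compartment[gene_id] = str(compartments[g_index])
            truth.causal_region[gene_id] = str(causal[g_index])
            truth.layouts[gene_id] = _GeneLayout(dense, isl, enhancer)
            g_index += 1
    truth.validate()
    return genes, islands, truth


def _grid(start: int, end: int, step: int) -> np.ndarray:
    """Positions on the 10 bp grid with the given step inside [start, end)."""
    lo = -(-start // 10) * 10
    return np.arange(lo, end, step, dtype=int)


def _layout_cpgs(
    genes: list[GeneModel], truth: TruthBundle, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place tagged CpG sites. Returns (chrom array, pos array, tag array);
    also records per-gene positions by tag in the truth layouts.

    Density: 10 bp in dense promoter blocks, islands and enhancers; 50 bp
    in promoters, exons and introns; 100 bp upstream; 300 bp intergenic.
    Priority on collision: dense > island > exon > intron > promoter >
    upstream > intergenic. Sparse background CpGs are kept one window
    (10 bp) clear of every dense feature so that called dip boundaries
    coincide exactly with the planted dense regions.
    """
    placed: dict[tuple[str, int], str] = {}
    tracked = ("dense", "island", "enhancer", "exon", "intron", "promoter")
    gene_pos: dict[str, dict[str, list[int]]] = {
        g.gene_id: {t: [] for t in tracked} for g in genes
    }
    # 10 bp guard band around dense features for sparse background CpGs
    guard: set[tuple[str, int]] = set()
    for g in genes:
        lay = truth.layouts[g.gene_id]
        feats = [lay.dense_block, lay.island] + ([lay.enhancer] if lay.enhancer else [])
        for f in feats:
            for p in _grid(max(0, f.start - 10), f.end + 10, 10):
                guard.add((g.chrom, int(p)))

    def put(chrom: str, positions: np.ndarray, tag: str, gene_id: str | None = None):
        dense_tag = tag in ("dense", "island", "enhancer")
        for p in positions:
            key = (chrom, int(p))
            if key in placed or (not dense_tag and key in guard):
                continue
            placed[key] = tag
            if gene_id is not None and tag in tracked:
                gene_pos[gene_id][tag].append(int(p))

    for g in genes:
        lay = truth.layouts[g.gene_id]
        put(g.chrom, _grid(lay.dense_block.start, lay.dense_block.end, 10), "dense", g.gene_id)
        put(g.chrom, _grid(lay.island.start, lay.island.end, 10), "island", g.gene_id)
        for ex in g.exons:
            put(g.chrom, _grid(ex.start, ex.end, 100), "exon", g.gene_id)
        for intr in g.introns():
            put(g.chrom, _grid(intr.start, intr.end, 30), "intron", g.gene_id)
        # promoter background CpGs on the upstream half only; the
        # downstream half belongs to exon 1
        if g.strand == "+":
            prom_half = (max(0, g.tss - 1000), g.tss)
        else:
            prom_half = (g.tss + 1, g.tss + 1001)
        put(g.chrom, _grid(prom_half[0], prom_half[1], 20), "promoter", g.gene_id)
        if g.strand == "+":
            up = (max(0, g.tss - 5000), g.tss - 1000)
        else:
            up = (g.tss + 1000, g.tss + 5000)
        put(g.chrom, _grid(up[0], up[1], 100), "upstream")
        if lay.enhancer is not None:
            put(g.chrom, _grid(lay.enhancer.start, lay.enhancer.end, 10), "enhancer", g.gene_id)

    chroms = sorted({g.chrom for g in genes})
    for chrom in chroms:
        put(chrom, np.arange(0, config.chrom_length_bp, 300, dtype=int), "intergenic")

    for gid, tags in gene_pos.items():
        truth.layouts[gid].cpg_by_tag = {t: np.array(sorted(v), dtype=int) for t, v in tags.items()}

    keys = sorted(placed)
    chrom_arr = np.array([k[0] for k in keys], dtype=object)
    pos_arr = np.array([k[1] for k in keys], dtype=int)
    tag_arr = np.array([placed[k] for k in keys], dtype=object)
    return chrom_arr, pos_arr, tag_arr


def _low_sets(
    genes: list[GeneModel], truth: TruthBundle
) -> tuple[set, set, set]:
    """Per-compartment sets of (chrom, pos) keys with planted low
    methylation: low in both compartments (active dense blocks, enhancers)
    and low only in the gene's expressed compartment (causal CpGs)."""
    low_both: set = set()
    low_by_comp: dict[str, set] = {GLOM: set(), TI: set()}
    for g in genes:
        lay = truth.layouts[g.gene_id]
        if truth.gene_states[g.gene_id] == "active_promoter":
            low_both.update((g.chrom, int(p)) for p in lay.cpg_by_tag["dense"])
        if lay.enhancer is not None:
            low_both.update((g.chrom, int(p)) for p in lay.cpg_by_tag["enhancer"])
        comp = truth.expressed_compartment[g.gene_id]
        cat = truth.causal_region[g.gene_id]
        tags = {"promoter": ("promoter", "dense"), "cpg_island": ("island",),
                "exon": ("exon",), "intron": ("intron",)}[cat]
        for t in tags:
            low_by_comp[comp].update((g.chrom, int(p)) for p in lay.cpg_by_tag[t])
    return low_both, low_by_comp[GLOM], low_by_comp[TI]


def simulate_methylation(
    genes: list[GeneModel], truth: TruthBundle, config: SimulationConfig
) -> CpGMethylationTrack:
    """Per-CpG binomial bisulfite counts for both compartments.

    Regional methylation is ``low_ml`` at planted low sites (active
    promoter blocks and enhancers in both compartments; each gene's causal
    CpGs in its expressed compartment) and ``high_ml`` elsewhere; per
    sample, numC ~ Binomial(coverage, ml) with Poisson coverage. Fills
    ``truth.planted_dips`` with the CpG-dense TI-low regions (>= 50 bp),
    the regions a TI dip caller should recover exactly.
    """
    rng = config.rng("methylation")
    chrom_arr, pos_arr, tag_arr = _layout_cpgs(genes, truth, config)
    low_both, low_glom, low_ti = _low_sets(genes, truth)
    keys = list(zip(chrom_arr.tolist(), pos_arr.tolist()))
    ml = {}
    for comp, low_comp in ((GLOM, low_glom), (TI, low_ti)):
        ml[comp] = np.array(
            [
                config.low_ml if (k in low_both or k in low_comp) else config.high_ml
                for k in keys
            ]
        )
    n_sites = len(pos_arr)
    n_samp = config.n_samples_per_compartment
    numC, numT = {}, {}
    for comp in (GLOM, TI):
        cov = rng.poisson(config.coverage_mean, size=(n_sites, n_samp)) + 1
        c = rng.binomial(cov, ml[comp][:, None])
        numC[comp] = c
        numT[comp] = cov - c

    # planted TI dips: CpG-dense low-TI regions, all >= 50 bp by construction
    dips = []
    for g in genes:
        lay = truth.layouts[g.gene_id]
        ti_causal = truth.expressed_compartment[g.gene_id] == TI
        cat = truth.causal_region[g.gene_id]
        if truth.gene_states[g.gene_id] == "active_promoter" or (
            ti_causal and cat == "promoter"  # dense block is part of the promoter move
        ):
            dips.append(lay.dense_block)
        if lay.enhancer is not None:
            dips.append(lay.enhancer)
        if ti_causal and cat == "cpg_island":
            dips.append(lay.island)
    truth.planted_dips = sorted(set(dips))
    truth.validate()

    return CpGMethylationTrack(
        chrom=chrom_arr,
        pos=pos_arr,
        numC=numC,
        numT=numT,
        samples={
            comp: [f"{comp}_{i+1}" for i in range(n_samp)] for comp in (GLOM, TI)
        },
    )


def simulate_mark_tracks(
    genes: list[GeneModel], truth: TruthBundle, config: SimulationConfig
) -> tuple[dict[str, MarkPeakSet], dict[str, SignalTrack]]:
    """Histone-mark and ATAC peak sets plus coverage tracks consistent with
    the planted states.

    Active promoter: H3K4me3 + H3K27ac + ATAC (H3K4me1 with probability
    ``h3k4me1_at_promoter_p``). Enhancer: H3K4me1 + H3K27ac + ATAC, no
    H3K4me3. Repressed promoter: H3K27me3 only. Background: nothing.
    Tracks are rectangular peaks of ``peak_height`` over a Poisson noise
    floor. Fills ``truth.region_states`` keyed by the anchor intervals.
    """
    rng = config.rng("marks")
    marks = ("H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3", "ATAC")
    peaks: dict[str, list[GenomicInterval]] = {m: [] for m in marks}
    chroms = sorted({g.chrom for g in genes})

    for g in genes:
        lay = truth.layouts[g.gene_id]
        state = truth.gene_states[g.gene_id]
        t0 = (lay.dense_block.start + lay.dense_block.end) // 2
        if state == "active_promoter":
            wide = GenomicInterval(g.chrom, t0 - 300, t0 + 300)
            anchor = GenomicInterval(g.chrom, t0 - 200, t0 + 200)
            peaks["H3K4me3"].append(wide)
            peaks["H3K27ac"].append(wide)
            peaks["ATAC"].append(anchor)
            if rng.random() < config.h3k4me1_at_promoter_p:
                peaks["H3K4me1"].append(wide)
            truth.region_states[anchor] = "active_promoter"
        elif state == "repressed":
            anchor = GenomicInterval(g.chrom, t0 - 500, t0 + 500)
            peaks["H3K27me3"].append(anchor)
            truth.region_states[anchor] = "repressed"
        else:
            truth.region_states[GenomicInterval(g.chrom, t0 - 200, t0 + 200)] = "background"
        if lay.enhancer is not None:
            e = lay.enhancer
            wide = GenomicInterval(g.chrom, e.start - 100, e.end + 100)
            anchor = GenomicInterval(g.chrom, e.start - 50, e.end + 50)
            peaks["H3K4me1"].append(wide)
            peaks["H3K27ac"].append(wide)
            peaks["ATAC"].append(anchor)
            truth.region_states[anchor] = "predicted_enhancer"

    peak_sets = {m: MarkPeakSet(m, sorted(p)) for m, p in peaks.items()}
    tracks = {}
    for m in marks:
        values = {}
        for chrom in chroms:
            arr = rng.poisson(config.noise_floor, size=config.chrom_length_bp).astype(float)
            for pk in peak_sets[m].peaks:
                if pk.chrom == chrom:
                    arr[pk.start : pk.end] += config.peak_height
            values[chrom] = arr
        tracks[m] = SignalTrack(m, values)
    return peak_sets, tracks


def simulate_cells(
    truth: TruthBundle,
    atac_peaks: MarkPeakSet,
    genes: list[GeneModel],
    config: SimulationConfig,
) -> tuple[CellByFeatureMatrix, CellByFeatureMatrix]:
    """Binarized peak-by-cell and count gene-by-cell matrices for the three
    cell types.

    Peaks get one of five planted classes: null (equal rate), up in
    adaptive/reference (acc_high vs acc_low), or new in adaptive/reference
    (acc_high in the owner, exactly 0 in the comparator — below any 2%
    threshold in expectation). DE genes get a 2^de_log2fc fold change in
    the adaptive type; dropout is applied to expression counts only.
    """
    rng = config.rng("cells")
    n = config.n_cells_per_type
    labels = np.repeat(list(CELL_TYPES), n)
    barcodes = [f"{t}_{i:04d}" for t in CELL_TYPES for i in range(n)]

    peak_ids = [f"peak_{i:04d}" for i in range(len(atac_peaks.peaks))]
    classes = np.array(
        ["null"] * len(peak_ids), dtype=object
    )
    order = rng.permutation(len(peak_ids))
    n_peaks = len(peak_ids)
    n_up = max(1, int(0.2 * n_peaks))
    n_new = max(1, int(0.1 * n_peaks))
    classes[order[:n_up]] = "up_in_adaptive"
    classes[order[n_up : 2 * n_up]] = "up_in_reference"
    classes[order[2 * n_up : 2 * n_up + n_new]] = "new_in_adaptive"
    classes[order[2 * n_up + n_new : 2 * n_up + 2 * n_new]] = "new_in_reference"

    rates = {
        "null": {"reference": config.acc_null, "adaptive": config.acc_null},
        "up_in_adaptive": {"reference": config.acc_low, "adaptive": config.acc_high},
        "up_in_reference": {"reference": config.acc_high, "adaptive": config.acc_low},
        "new_in_adaptive": {"reference": 0.0, "adaptive": config.acc_high},
        "new_in_reference": {"reference": config.acc_high, "adaptive": 0.0},
    }
    acc = np.zeros((n_peaks, 3 * n), dtype=np.int8)
    for j, t in enumerate(CELL_TYPES):
        col = slice(j * n, (j + 1) * n)
        p = np.array(
            [
                rates[c].get(t, config.acc_other) if t != "other" else config.acc_other
                for c in classes
            ]
        )
        acc[:, col] = rng.random((n_peaks, n)) < p[:, None]
    for i, c in enumerate(classes):
        truth.da_truth[peak_ids[i]] = c if c in ("up_in_adaptive", "up_in_reference") else (
            "up_in_adaptive" if c == "new_in_adaptive" else (
                "up_in_reference" if c == "new_in_reference" else "null"
            )
        )
        truth.new_peak_truth[peak_ids[i]] = (
            "adaptive" if c == "new_in_adaptive" else ("reference" if c == "new_in_reference" else None)
        )
    peak_mat = CellByFeatureMatrix(
        sp.csr_matrix(acc), peak_ids, barcodes, labels, list(atac_peaks.peaks)
    )

    # expression: disjoint marker sets per cell type so that type profiles
    # are distinguishable (required for signature deconvolution), plus
    # unplanted null genes for false-positive accounting. Background filler
    # genes keep marker expression a small fraction of each cell's library,
    # as in a real transcriptome — otherwise library-size normalization
    # induces compositional shifts in null genes.
    gene_ids = [g.gene_id for g in genes] + [
        f"bg_{i:04d}" for i in range(config.n_background_genes)
    ]
    n_genes = len(gene_ids)
    n_genomic = len(genes)
    # marker sets shrink proportionally on small gene panels
    k = min(config.n_de_genes, max(1, n_genomic // 2))
    n_sec = min(config.n_markers_secondary, max(0, (n_genomic - k) // 2))
    lam = rng.uniform(0.5, 5.0, size=n_genes)
    # stratify markers over chromatin states so each cell type keeps a
    # fair share of active-promoter genes (markers of a cell state are
    # expressed there, hence mostly active chromatin)
    active = [i for i, g in enumerate(genes)
              if truth.gene_states[g.gene_id] == "active_promoter"]
    inactive = [i for i in range(n_genomic) if i not in set(active)]
    active = list(rng.permutation(active))
    inactive = list(rng.permutation(inactive))
    marker_of = np.array(["null"] * n_genes, dtype=object)
    for ctype, size in (("adaptive", k), ("reference", n_sec), ("other", n_sec)):
        n_act = min(len(active), int(np.ceil(0.6 * size)))
        chosen = [active.pop() for _ in range(n_act)]
        chosen += [inactive.pop() for _ in range(min(size - n_act, len(inactive)))]
        marker_of[chosen] = ctype
    # balance the planted marker boost mass between the two compared states
    # so library-size normalization leaves null genes exactly null in the
    # adaptive-vs-reference contrast
    fold = 2.0 ** config.de_log2fc
    boost_a = float((lam[marker_of == "adaptive"] * (fold - 1)).sum())
    lam_r = float(lam[marker_of == "reference"].sum())
    gamma = (boost_a / lam_r + 1) / fold if lam_r > 0 else 1.0
    per_type_fold = {"adaptive": fold, "reference": fold * gamma, "other": fold}
    counts = np.zeros((n_genes, 3 * n), dtype=np.int32)
    for j, t in enumerate(CELL_TYPES):
        col = slice(j * n, (j + 1) * n)
        lam_t = np.where(marker_of == t, lam * per_type_fold[t], lam)
        counts[:, col] = rng.poisson(lam_t[:, None], size=(n_genes, n))
    if config.dropout > 0:
        keep = rng.random(counts.shape) >= config.dropout
        counts = counts * keep
    for i, gid in enumerate(gene_ids):
        truth.de_truth[gid] = (
            f"up_in_{marker_of[i]}" if marker_of[i] != "null" else "null"
        )
    gene_mat = CellByFeatureMatrix(sp.csr_matrix(counts), gene_ids, list(barcodes), labels)
    return peak_mat, gene_mat


def _pooled_ml(
    track: CpGMethylationTrack, intervals: list[GenomicInterval], compartment: str
) -> float:
    mask = np.zeros(track.n_sites(), dtype=bool)
    for iv in intervals:
        mask |= track.site_mask(iv)
    c = track.numC[compartment][mask].sum()
    t = track.numT[compartment][mask].sum()
    return math.nan if c + t == 0 else float(c / (c + t))


def causal_intervals(gene: GeneModel, truth: TruthBundle) -> list[GenomicInterval]:
    """The catalog intervals of a gene's planted causal category."""
    cat = truth.causal_region[gene.gene_id]
    lay = truth.layouts[gene.gene_id]
    if cat == "promoter":
        return [GenomicInterval(gene.chrom, max(0, gene.tss - 1000), gene.tss + 1000)]
    if cat == "cpg_island":
        return [lay.island]
    if cat == "exon":
        return list(gene.exons)
    return gene.introns() or [gene.span]


def simulate_expression(
    genes: list[GeneModel],
    truth: TruthBundle,
    track: CpGMethylationTrack,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Bulk GLOM/TI expression anti-correlated with causal-region
    methylation: log2FC = -slope * Hyper(causal region) + Gaussian noise
    with sd = ``expression_noise`` x sd of the noiseless signal.
    """
    rng = config.rng("expression")
    signals = []
    for g in genes:
        ivs = causal_intervals(g, truth)
        mg = _pooled_ml(track, ivs, GLOM)
        mt = _pooled_ml(track, ivs, TI)
        h = hyper(mg, mt) if math.isfinite(mg) and math.isfinite(mt) else 0.0
        signals.append(-config.expression_slope * h)
    signals = np.array(signals)
    sd = signals.std()
    noise = rng.normal(0.0, config.expression_noise * sd, size=len(signals)) if sd > 0 else 0.0
    log2fc = signals + noise
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "expr_GLOM": 5.0 + log2fc / 2,
            "expr_TI": 5.0 - log2fc / 2,
            "log2FC": log2fc,
        }
    ).set_index("gene_id")


def simulate_bulk_mixture(
    profiles: pd.DataFrame,
    mixture: dict[str, float],
    noise_frac: float = 0.05,
    seed: int = 0,
) -> pd.Series:
    """Bulk profile as a planted convex mixture of per-type profiles plus
    multiplicative Gaussian noise of relative sd ``noise_frac``."""
    rng = np.random.default_rng([int(seed), _STREAMS["bulk"]])
    w = np.array([mixture[t] for t in profiles.columns])
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("mixture must sum to 1")
    y = profiles.to_numpy(dtype=float) @ w
    if noise_frac > 0:
        y = y * (1.0 + rng.normal(0.0, noise_frac, size=len(y)))
    return pd.Series(np.maximum(y, 0.0), index=profiles.index, name="bulk")


@dataclass
class SyntheticDataset:
    """Everything one simulated study emits, plus its ground truth."""

    config: SimulationConfig
    genes: list[GeneModel]
    cpg_islands: list[GenomicInterval]
    truth: TruthBundle
    methylation: CpGMethylationTrack
    mark_peaks: dict[str, MarkPeakSet]
    mark_tracks: dict[str, SignalTrack]
    peak_matrix: CellByFeatureMatrix
    gene_matrix: CellByFeatureMatrix
    expression: pd.DataFrame


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Run every generator stage in dependency order."""
    genes, islands, truth = generate_genome(config)
    meth = simulate_methylation(genes, truth, config)
    peaks, tracks = simulate_mark_tracks(genes, truth, config)
    peak_mat, gene_mat = simulate_cells(truth, peaks["ATAC"], genes, config)
    expr = simulate_expression(genes, truth, meth, config)
    return SyntheticDataset(
        config, genes, islands, truth, meth, peaks, tracks, peak_mat, gene_mat, expr
    )
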