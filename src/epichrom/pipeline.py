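"""End-to-end driver: generate (or load) the multi-modal dataset, then run
the stages in dependency order — region annotation, region-summative
methylation with differential testing, dip calling, Gisch peak coding,
chromatin-state annotation, cross-technology kappa/Fisher agreement,
cell-state DE/DA/new-peak analysis, signature deconvolution, and the
best-fit methylation-expression model — collecting per-stage outputs and
a truth-recovery report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cellstate as cs
from . import chromatin as ch
from . import concordance as cc
from . import io as eio
from . import methylation as me
from .config import PipelineConfig
from .genome import GenomicInterval, annotate_gene_regions, make_promoters
from .simulate import CELL_TYPES, SyntheticDataset, simulate_all, simulate_bulk_mixture

log = logging.getLogger("epichrom")

BESTFIT_CATEGORIES = ("promoter", "cpg_island", "exon", "intron")


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: SyntheticDataset
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    dips: list[GenomicInterval] = field(default_factory=list)
    state_calls: list = field(default_factory=list)
    report: dict = field(default_factory=dict)


def _category_intervals(gene, catalog, category):
    return [e.interval for e in catalog.for_gene(gene.gene_id) if e.category == category]


def region_methylation_table(ds, catalog, cfg: PipelineConfig) -> pd.DataFrame:
    """Per gene x category: pooled ml per compartment, Hyper, Welch t-test
    over per-sample pooled ml, multiple-testing correction across rows."""
    track = me.filter_cpgs(ds.methylation, cfg.min_coverage)
    rows = []
    glom_ml, ti_ml = [], []
    for g in ds.genes:
        for cat in ("whole_gene",) + BESTFIT_CATEGORIES:
            ivs = _category_intervals(g, catalog, cat)
            if not ivs:
                continue
            mg = me.pooled_mask_ml(track, ivs, me.GLOM)
            mt = me.pooled_mask_ml(track, ivs, me.TI)
            h = (
                me.hyper(mg, mt, cfg.beta)
                if np.isfinite(mg) and np.isfinite(mt)
                else np.nan
            )
            rows.append(
                {"gene_id": g.gene_id, "category": cat, "ml_GLOM": mg, "ml_TI": mt, "hyper": h}
            )
            glom_ml.append(me.per_sample_pooled_ml(track, ivs, me.GLOM))
            ti_ml.append(me.per_sample_pooled_ml(track, ivs, me.TI))
    stats_df = me.diff_region_methylation(
        np.vstack(glom_ml), np.vstack(ti_ml), correction=cfg.correction
    )
    return pd.concat([pd.DataFrame(rows), stats_df], axis=1)


def call_all_dips(ds, cfg: PipelineConfig, compartment: str = me.TI) -> list[GenomicInterval]:
    track = me.filter_cpgs(ds.methylation, cfg.min_coverage)
    dips: list[GenomicInterval] = []
    for chrom in sorted(set(track.chrom.tolist())):
        ml = me.windowed_methylation(
            track, compartment, chrom, ds.config.chrom_length_bp, cfg.dip_window_bp
        )
        dips.extend(
            me.call_methyl_dips(
                ml, chrom, cfg.dip_window_bp, cfg.dip_max_ml, cfg.dip_min_len_bp
            )
        )
    return dips


def chromatin_states(ds, dips, cfg: PipelineConfig):
    """State calls over the assessment anchors (ATAC plus H3K27me3 peaks)."""
    anchors = sorted(ds.mark_peaks["ATAC"].peaks + ds.mark_peaks["H3K27me3"].peaks)
    promoters = make_promoters(ds.genes, cfg.promoter_width)
    bodies = [g.span for g in ds.genes]
    mark_peaks = {m: ds.mark_peaks[m].peaks for m in ch.MARKS}
    return ch.annotate_states(
        anchors, mark_peaks, promoters, bodies, dips, cfg.strict_enhancer
    )


def cross_technology_kappa(ds, catalog, dips, cfg: PipelineConfig) -> pd.DataFrame:
    """Per-gene Cohen's kappa between open-chromatin (ATAC), H3K4me3 and
    methylation-dip codings over the gene's region units."""
    results = []
    for g in ds.genes:
        units = catalog.gene_units(g.gene_id)
        if len(units) < 2:
            continue
        unit_keys = [
            (e.interval.chrom, e.interval.start, e.interval.end, e.category) for e in units
        ]
        calls = {}
        for tech, track in (("snATAC", ds.mark_tracks["ATAC"]), ("H3K4me3", ds.mark_tracks["H3K4me3"])):
            calls[tech] = ch.gisch_filter(track, g, units, mode="peak")
        dip_call = {}
        for i, e in enumerate(units):
            hit = any(e.interval.overlaps(d) for d in dips)
            dip_call[i] = "dip" if hit else "absent"
        calls["DNAm_dip"] = dip_call
        coding = cc.code_gene_regions(g.gene_id, unit_keys, calls)
        for pair in (("snATAC", "H3K4me3"), ("snATAC", "DNAm_dip"), ("H3K4me3", "DNAm_dip")):
            results.append(cc.kappa_for_gene(coding, *pair))
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "pair": [f"{r.tech_a}|{r.tech_b}" for r in results],
            "kappa": [r.kappa for r in results],
            "n_units": [r.n_units for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )


def genomewide_fisher(ds, dips, cfg: PipelineConfig) -> pd.DataFrame:
    """Pairwise Fisher association between feature sets over fixed bins."""
    n_bins = ds.config.chrom_length_bp // cfg.fisher_bin_bp
    chroms = sorted({g.chrom for g in ds.genes})
    feature_sets = {m: ds.mark_peaks[m].peaks for m in ("ATAC",) + ch.MARKS}
    feature_sets["DNAm_dip"] = dips

    def flags(features):
        out = []
        for chrom in chroms:
            f = np.zeros(n_bins, dtype=bool)
            for iv in features:
                if iv.chrom == chrom:
                    f[iv.start // cfg.fisher_bin_bp : (iv.end - 1) // cfg.fisher_bin_bp + 1] = True
            out.append(f)
        return np.concatenate(out)

    vecs = {name: flags(feats) for name, feats in feature_sets.items()}
    rows = []
    names = list(vecs)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            orat, p = cc.fisher_association(vecs[a], vecs[b])
            rows.append({"feature_a": a, "feature_b": b, "odds_ratio": orat, "p": p})
    return pd.DataFrame(rows)


def cellstate_stage(ds, cfg: PipelineConfig):
    de = cs.de_genes_wilcoxon(
        ds.gene_matrix, "adaptive", "reference", cfg.alpha, cfg.min_pct
    )
    da = cs.da_peaks_lr(ds.peak_matrix, "adaptive", "reference", cfg.alpha)
    cs.find_new_peaks(da, "adaptive", "reference", cfg.new_peak_threshold)
    da_df = pd.DataFrame(
        {
            "peak": [r.peak for r in da],
            "frac_adaptive": [r.frac_a for r in da],
            "frac_reference": [r.frac_b for r in da],
            "avg_log2FC": [r.avg_log2fc for r in da],
            "p": [r.p for r in da],
            "p_bonferroni": [r.p_bonferroni for r in da],
            "is_DA": [r.is_da for r in da],
            "is_new_peak": [r.is_new_peak for r in da],
            "new_peak_owner": [r.new_peak_owner for r in da],
        }
    ).set_index("peak")
    auc = pd.DataFrame(
        {
            g.gene_id: cs.gene_open_chromatin_auc(ds.peak_matrix, g, cfg.tss_window_bp)
            for g in ds.genes
        }
    ).T
    return de, da, da_df, auc


def deconvolution_stage(ds, cfg: PipelineConfig):
    """Marker signature from per-type DE vs rest, then mixture recovery of
    a bulk profile simulated at the planted proportions."""
    mat = ds.gene_matrix
    de_tables = {}
    for t in CELL_TYPES:
        labels = np.where(mat.labels == t, t, "rest")
        tmp = cs.CellByFeatureMatrix(
            mat.matrix, mat.feature_ids, mat.barcodes, labels, mat.feature_intervals
        )
        table = cs.de_genes_wilcoxon(tmp, t, "rest", cfg.alpha, cfg.min_pct)
        markers = table[table["significant"] & (table["avg_log2FC"] > 0)]
        de_tables[t] = markers.sort_values("avg_log2FC", ascending=False)
    promoters = make_promoters(ds.genes, cfg.promoter_width)
    prom_by_gene = dict(zip([g.gene_id for g in ds.genes], promoters))
    histone = [
        p for m in ("H3K27ac", "H3K4me1", "H3K4me3") for p in ds.mark_peaks[m].peaks
    ]
    promoter_peak_genes = {
        gid for gid, prom in prom_by_gene.items() if any(prom.overlaps(p) for p in histone)
    }
    sums, _ = cs.pseudobulk(mat, list(CELL_TYPES))
    n_per_type = {t: (mat.labels == t).sum() for t in CELL_TYPES}
    profiles = sums / pd.Series(n_per_type)
    sig = cs.build_signature(
        de_tables,
        promoter_peak_genes,
        profiles,
        top_fraction=cfg.deconv_top_fraction,
        min_markers=cfg.deconv_min_markers,
    )
    bulk = simulate_bulk_mixture(
        sig.profiles, ds.truth.mixture, cfg.deconv_noise, cfg.seed
    )
    est = cs.deconvolve(sig, bulk)
    return sig, est


def bestfit_stage(ds, region_table: pd.DataFrame):
    meth = region_table.pivot_table(
        index="gene_id", columns="category", values="hyper"
    )[list(BESTFIT_CATEGORIES)]
    expr = ds.expression.loc[meth.index, "log2FC"]
    return me.best_fit_expression_model(meth, expr)


def _truth_recovery(ds, result: "PipelineResult") -> dict:
    truth = ds.truth
    rep: dict = {}
    rep["n_dips_called"] = len(result.dips)
    rep["n_dips_planted"] = len(truth.planted_dips)
    rep["dips_exact_match"] = sorted(result.dips) == sorted(truth.planted_dips)

    state_ok = state_total = 0
    for call in result.state_calls:
        t = truth.region_states.get(call.peak)
        if t is None:
            continue
        state_total += 1
        state_ok += int(call.state == t)
    rep["state_accuracy"] = state_ok / state_total if state_total else np.nan

    da_df = result.tables["da_peaks"]
    truth_up = {
        p: lbl for p, lbl in truth.da_truth.items() if lbl != "null"
    }
    called_da = da_df[da_df["is_DA"]]
    dir_ok = 0
    for p, row in called_da.iterrows():
        want = truth_up.get(p)
        if want == "up_in_adaptive" and row["avg_log2FC"] > 0:
            dir_ok += 1
        elif want == "up_in_reference" and row["avg_log2FC"] < 0:
            dir_ok += 1
    rep["n_da_called"] = int(len(called_da))
    rep["n_da_planted"] = len(truth_up)
    rep["da_direction_correct"] = dir_ok
    np_called = set(da_df[da_df["is_new_peak"]].index)
    np_truth = {p for p, o in truth.new_peak_truth.items() if o is not None}
    tp = len(np_called & np_truth)
    rep["new_peak_precision"] = tp / len(np_called) if np_called else np.nan
    rep["new_peak_recall"] = tp / len(np_truth) if np_truth else np.nan

    de = result.tables["de_genes"]
    sig_genes = set(de[de["significant"]].index)
    planted_a = {g for g, l in truth.de_truth.items() if l == "up_in_adaptive"}
    planted_any = {g for g, l in truth.de_truth.items() if l in ("up_in_adaptive", "up_in_reference")}
    rep["de_recovered_adaptive"] = len(sig_genes & planted_a)
    rep["de_planted_adaptive"] = len(planted_a)
    null_genes = {g for g, l in truth.de_truth.items() if l in ("null", "up_in_other")}
    rep["de_false_positives"] = len(sig_genes & null_genes)
    rep["de_planted_recovered_any"] = len(sig_genes & planted_any)

    est = result.tables["mixture_estimate"]["proportion"]
    err = {t: abs(est.get(t, 0.0) - truth.mixture[t]) for t in truth.mixture}
    rep["deconv_max_abs_error"] = max(err.values())

    bf = result.tables["best_fit"]
    agree = sum(
        bf.at[g, "selected_category"] == truth.causal_region[g] for g in bf.index
    )
    rep["bestfit_recovery"] = agree / len(bf)
    rep["bestfit_concordance"] = float(result.report.get("bestfit_concordance", np.nan))
    return rep


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage; optionally write all outputs under ``outdir``."""
    t0 = time.time()
    ds = simulate_all(config.simulation)
    result = PipelineResult(config, ds)
    cfg_hash = eio.config_hash(config.to_dict())
    log.info("simulated dataset: %d genes, %d CpGs, %d peaks",
             len(ds.genes), ds.methylation.n_sites(), len(ds.peak_matrix.feature_ids))

    catalog = annotate_gene_regions(
        ds.genes,
        ds.cpg_islands,
        promoter_width=config.promoter_width,
        chrom_sizes={c: ds.config.chrom_length_bp for c in sorted({g.chrom for g in ds.genes})},
    )
    region_table = region_methylation_table(ds, catalog, config)
    result.tables["region_methylation"] = region_table
    log.info("region methylation: %d rows", len(region_table))

    result.dips = call_all_dips(ds, config)
    log.info("dips called: %d", len(result.dips))

    result.state_calls = chromatin_states(ds, result.dips, config)
    result.tables["states"] = pd.DataFrame(
        {
            "chrom": [c.peak.chrom for c in result.state_calls],
            "start": [c.peak.start for c in result.state_calls],
            "end": [c.peak.end for c in result.state_calls],
            "marks": ["+".join(sorted(c.marks_present)) for c in result.state_calls],
            "in_promoter": [c.in_promoter for c in result.state_calls],
            "has_dip": [c.has_dip for c in result.state_calls],
            "state": [c.state for c in result.state_calls],
        }
    )

    kappa_df = cross_technology_kappa(ds, catalog, result.dips, config)
    result.tables["kappa"] = kappa_df
    result.tables["fisher"] = genomewide_fisher(ds, result.dips, config)

    de, da, da_df, auc = cellstate_stage(ds, config)
    result.tables["de_genes"] = de
    result.tables["da_peaks"] = da_df
    result.tables["gene_open_chromatin_auc"] = auc

    sig, est = deconvolution_stage(ds, config)
    result.tables["mixture_estimate"] = est.to_frame()

    bf = bestfit_stage(ds, region_table)
    result.tables["best_fit"] = pd.DataFrame(
        {"selected_category": bf.selected, "predicted_log2FC": bf.predicted}
    )
    result.report["bestfit_concordance"] = bf.concordance
    result.report["category_r"] = bf.category_r

    for pair, sub in kappa_df.groupby("pair"):
        g_t, _ = cc.kappa_summary(
            [cc.KappaResult("", "", "", k, 0, np.zeros((2, 2))) for k in sub["kappa"]]
        )
        result.report[f"G_T[{pair}]"] = g_t

    result.report.update(_truth_recovery(ds, result))
    result.report["runtime_s"] = round(time.time() - t0, 2)
    result.report["config_hash"] = cfg_hash
    result.report["seed"] = config.seed

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in result.tables.items():
            eio.write_table(df, outdir / f"{name}.tsv", cfg_hash, config.seed)
        eio.write_bed(
            result.dips, outdir / "dips.bed",
            header=eio.provenance_header(cfg_hash, config.seed),
        )
        with open(outdir / "report.json", "w") as fh:
            json.dump(result.report, fh, indent=2, default=str)
        log.info("outputs written to %s", outdir)
    return result
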