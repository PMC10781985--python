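"""Generate the default synthetic two-compartment kidney dataset and write
it (plus its ground truth) under results/data/.

The dataset: 50 genes on two 1 Mb chromosomes, per-CpG bisulfite counts
for 4 GLOM and 4 TI samples, five mark peak sets and coverage tracks,
binarized snATAC peak-by-cell and gene-by-cell matrices for three cell
types (reference / adaptive / other), and a bulk expression table tied to
each gene's causal methylation region.
"""

import argparse
import json
from pathlib import Path

from epichrom import io as eio
from epichrom.config import PipelineConfig
from epichrom.simulate import simulate_all


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed)
    ds = simulate_all(cfg.simulation)
    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    eio.write_gtf(ds.genes, out / "genes.gtf")
    eio.write_bed(ds.cpg_islands, out / "cpg_islands.bed")
    eio.write_cpg_tsv(ds.methylation, out / "cpg_counts.tsv")
    for mark, ps in ds.mark_peaks.items():
        eio.write_bed(ps.peaks, out / f"peaks_{mark}.bed")
    eio.write_cell_matrix(ds.peak_matrix, out / "peak_matrix")
    eio.write_cell_matrix(ds.gene_matrix, out / "gene_matrix")
    ds.expression.to_csv(out / "expression.tsv", sep="\t")
    truth = {
        "gene_states": ds.truth.gene_states,
        "planted_dips": [[d.chrom, d.start, d.end] for d in ds.truth.planted_dips],
        "causal_region": ds.truth.causal_region,
        "mixture": ds.truth.mixture,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    print(
        f"wrote {len(ds.genes)} genes, {ds.methylation.n_sites()} CpGs, "
        f"{len(ds.peak_matrix.feature_ids)} peaks, "
        f"{len(ds.truth.planted_dips)} planted dips to {out}"
    )


if __name__ == "__main__":
    main()
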