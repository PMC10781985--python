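"""Readers and writers for the plain-text interchange formats: BED and
bedGraph (native 0-based half-open), GTF (converted from 1-based inclusive
on read), per-CpG count TSV, MatrixMarket cell matrices, and the truth /
report JSON. Every table written by the pipeline carries a provenance
header line with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .cellstate import CellByFeatureMatrix
from .chromatin import MarkPeakSet, SignalTrack
from .genome import GeneModel, GenomicInterval
from .methylation import CpGMethylationTrack

__all__ = [
    "read_bed",
    "write_bed",
    "read_bedgraph_track",
    "write_bedgraph",
    "read_gtf",
    "write_gtf",
    "read_cpg_tsv",
    "write_cpg_tsv",
    "read_cell_matrix",
    "write_cell_matrix",
    "config_hash",
    "provenance_header",
    "write_table",
]


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(cfg_hash: str, seed: int) -> str:
    return f"# epichrom config={cfg_hash} seed={seed}"


def write_table(df: pd.DataFrame, path: str | Path, cfg_hash: str = "", seed: int = 0) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if cfg_hash:
            fh.write(provenance_header(cfg_hash, seed) + "\n")
        df.to_csv(fh, sep="\t", index=True)


# ---------------------------------------------------------------- BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3+ reader; strand taken from column 6 when present. Rejects
    records whose coordinates look 1-based inclusive (end < start)."""
    out = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        chrom, start, end = f[0], int(f[1]), int(f[2])
        if end <= start:
            raise ValueError(
                f"{path}:{line_no}: non-positive width interval "
                f"[{start},{end}) — is this file 1-based?"
            )
        strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
        out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(
    intervals: list[GenomicInterval],
    path: str | Path,
    names: list[str] | None = None,
    header: str = "",
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------- bedGraph


def read_bedgraph_track(
    path: str | Path, mark: str, chrom_lengths: dict[str, int]
) -> SignalTrack:
    """bedGraph -> dense per-base SignalTrack. Unsorted input is accepted;
    intervals are applied in file order."""
    values = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        chrom, start, end, value = line.split("\t")
        start, end = int(start), int(end)
        if end <= start:
            raise ValueError(f"{path}: non-positive width interval [{start},{end})")
        values[chrom][start:end] = float(value)
    return SignalTrack(mark, values)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Run-length encoded bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:g}\n")


# ---------------------------------------------------------------- GTF


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Minimal GTF reader: gene / exon / five_prime_utr / three_prime_utr
    features keyed by gene_id, converted to 0-based half-open."""
    spans: dict[str, tuple] = {}
    exons: dict[str, list] = {}
    utr5: dict[str, list] = {}
    utr3: dict[str, list] = {}
    symbols: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        chrom, feature, start, end, strand, attrs = f[0], f[2], int(f[3]), int(f[4]), f[6], f[8]
        gid = _gtf_attr(attrs, "gene_id")
        iv = GenomicInterval(chrom, start - 1, end, strand)
        if feature == "gene":
            spans[gid] = iv
            symbols[gid] = _gtf_attr(attrs, "gene_name") or gid
        elif feature == "exon":
            exons.setdefault(gid, []).append(iv)
        elif feature == "five_prime_utr":
            utr5.setdefault(gid, []).append(iv)
        elif feature == "three_prime_utr":
            utr3.setdefault(gid, []).append(iv)
    genes = []
    for gid, span in spans.items():
        genes.append(
            GeneModel(
                gid,
                symbols.get(gid, gid),
                span.strand,
                span,
                sorted(exons.get(gid, [])),
                sorted(utr5.get(gid, [])),
                sorted(utr3.get(gid, [])),
            )
        )
    return genes


def _gtf_attr(attrs: str, key: str) -> str:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip('"')
    return ""


def write_gtf(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\tepichrom\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{g.chrom}\tepichrom\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------- CpG TSV


def write_cpg_tsv(track: CpGMethylationTrack, path: str | Path) -> None:
    track.to_frame().to_csv(path, sep="\t", index=False)


def read_cpg_tsv(path: str | Path) -> CpGMethylationTrack:
    df = pd.read_csv(path, sep="\t")
    sites = df[["chrom", "pos"]].drop_duplicates().sort_values(["chrom", "pos"])
    chrom = sites["chrom"].to_numpy(dtype=object)
    pos = sites["pos"].to_numpy(dtype=int)
    index = {(c, p): i for i, (c, p) in enumerate(zip(chrom, pos))}
    numC: dict[str, np.ndarray] = {}
    numT: dict[str, np.ndarray] = {}
    samples: dict[str, list[str]] = {}
    for comp, sub in df.groupby("compartment"):
        names = sorted(sub["sample"].unique())
        samples[comp] = names
        c_arr = np.zeros((len(pos), len(names)), dtype=int)
        t_arr = np.zeros((len(pos), len(names)), dtype=int)
        for j, name in enumerate(names):
            s = sub[sub["sample"] == name]
            rows = [index[(c, p)] for c, p in zip(s["chrom"], s["pos"])]
            c_arr[rows, j] = s["numC"].to_numpy()
            t_arr[rows, j] = s["numT"].to_numpy()
        numC[comp], numT[comp] = c_arr, t_arr
    return CpGMethylationTrack(chrom, pos, numC, numT, samples)


# ---------------------------------------------------------------- cell matrices


def write_cell_matrix(mat: CellByFeatureMatrix, outdir: str | Path) -> None:
    """10x-style trio (matrix.mtx, features.tsv, barcodes.tsv) plus a
    labels.tsv with the cell-type label per barcode."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(mat.matrix))
    with open(outdir / "features.tsv", "w") as fh:
        for i, fid in enumerate(mat.feature_ids):
            if mat.feature_intervals is not None:
                iv = mat.feature_intervals[i]
                fh.write(f"{fid}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{fid}\n")
    with open(outdir / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(mat.barcodes) + "\n")
    pd.DataFrame({"barcode": mat.barcodes, "label": mat.labels}).to_csv(
        outdir / "labels.tsv", sep="\t", index=False
    )


def read_cell_matrix(outdir: str | Path) -> CellByFeatureMatrix:
    outdir = Path(outdir)
    matrix = sp.csr_matrix(sio.mmread(outdir / "matrix.mtx"))
    feat_lines = (outdir / "features.tsv").read_text().splitlines()
    feature_ids, intervals = [], []
    has_coords = True
    for line in feat_lines:
        f = line.split("\t")
        feature_ids.append(f[0])
        if len(f) >= 4:
            intervals.append(GenomicInterval(f[1], int(f[2]), int(f[3])))
        else:
            has_coords = False
    barcodes = (outdir / "barcodes.tsv").read_text().split()
    if matrix.shape[0] != len(feature_ids):
        raise ValueError(
            f"{outdir}: matrix has {matrix.shape[0]} features but features.tsv "
            f"lists {len(feature_ids)}"
        )
    if matrix.shape[1] != len(barcodes):
        raise ValueError(
            f"{outdir}: matrix has {matrix.shape[1]} cells but barcodes.tsv "
            f"lists {len(barcodes)}"
        )
    labels_df = pd.read_csv(outdir / "labels.tsv", sep="\t")
    labels = labels_df.set_index("barcode").loc[barcodes, "label"].to_numpy()
    return CellByFeatureMatrix(
        matrix, feature_ids, barcodes, labels, intervals if has_coords else None
    )
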