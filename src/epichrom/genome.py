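"""Genomic coordinate substrate: intervals, gene models, and the per-gene
region taxonomy (whole gene, promoter, 1-5 kb upstream, exons, introns,
UTRs, CpG islands/shores/shelves/open sea) that every summarisation in the
pipeline runs over.

All coordinates are 0-based half-open internally. BED is read natively;
GTF is converted on read (1-based inclusive -> 0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "RegionEntry",
    "RegionCatalog",
    "REGION_CATEGORIES",
    "make_promoters",
    "annotate_gene_regions",
    "overlap_intervals",
    "merge_intervals",
    "subtract_intervals",
]

REGION_CATEGORIES = (
    "whole_gene",
    "upstream_1to5kb",
    "promoter",
    "exon",
    "intron",
    "utr5",
    "utr3",
    "cpg_island",
    "cpg_shore",
    "cpg_shelf",
    "cpg_inter",
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``.

    ``strand`` is '+', '-' or '.' (unstranded). Ordering is
    (chrom, start, end), which fixes every tie-break in the package.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GeneModel:
    """A gene with its span, TSS and ordered exon structure.

    Exons are disjoint, sorted, and contained in the span. The TSS is the
    span's 5' end: ``span.start`` on '+', ``span.end - 1`` on '-'.
    """

    gene_id: str
    symbol: str
    strand: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.span.chrom:
                raise ValueError("exon on wrong chromosome")
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError("exon outside gene span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError("exons must be sorted and disjoint")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def chrom(self) -> str:
        return self.span.chrom

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons; empty for single-exon genes."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass(frozen=True)
class RegionEntry:
    """One labeled interval of the catalog: a category plus its owning gene
    (empty gene_id for the gene-free cpg_inter category)."""

    gene_id: str
    category: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.category not in REGION_CATEGORIES:
            raise ValueError(f"unknown region category {self.category!r}")


class RegionCatalog:
    """Per-gene labeled intervals in the annotatr-style taxonomy."""

    def __init__(self, entries: Iterable[RegionEntry] = ()) -> None:
        self.entries: list[RegionEntry] = list(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RegionEntry]:
        return iter(self.entries)

    def add(self, gene_id: str, category: str, interval: GenomicInterval) -> None:
        self.entries.append(RegionEntry(gene_id, category, interval))

    def for_gene(self, gene_id: str) -> list[RegionEntry]:
        return [e for e in self.entries if e.gene_id == gene_id]

    def by_category(self, category: str) -> list[RegionEntry]:
        return [e for e in self.entries if e.category == category]

    def gene_units(self, gene_id: str) -> list[RegionEntry]:
        """The gene's codable region units (promoter, upstream block, exons,
        introns), position-sorted — the granularity of the Gisch filter and
        of the cross-technology region coding."""
        units = [
            e
            for e in self.for_gene(gene_id)
            if e.category in ("promoter", "upstream_1to5kb", "exon", "intron")
        ]
        return sorted(units, key=lambda e: e.interval)


def make_promoters(
    genes: Sequence[GeneModel], width: int = 2000
) -> list[GenomicInterval]:
    """Promoters as ``width`` bp windows centered on the TSS, clipped at 0.

    The 2 kb default window is centered regardless of strand; only the TSS
    position itself is strand-dependent.
    """
    if width <= 0 or width % 2:
        raise ValueError("width must be even and positive")
    half = width // 2
    out = []
    for g in genes:
        start = max(0, g.tss - half)
        out.append(GenomicInterval(g.chrom, start, g.tss + half, g.strand))
    return out


def _upstream_block(gene: GeneModel, near: int = 1000, far: int = 5000):
    """Strand-aware 1-5 kb upstream block, clipped at 0; None if fully clipped."""
    if gene.strand == "+":
        start, end = gene.tss - far, gene.tss - near
    else:
        start, end = gene.tss + near + 1, gene.tss + far + 1
    start = max(0, start)
    if start >= end:
        return None
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, non-overlapping list (strand dropped)."""
    ivs = sorted(intervals, key=lambda x: (x.chrom, x.start, x.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference a \\ b over merged inputs."""
    a_m = merge_intervals(a)
    b_m = merge_intervals(b)
    out: list[GenomicInterval] = []
    for iv in a_m:
        cursor = iv.start
        for cut in b_m:
            if cut.chrom != iv.chrom or cut.end <= cursor or cut.start >= iv.end:
                continue
            if cut.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, cut.start))
            cursor = max(cursor, cut.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return out


def annotate_gene_regions(
    genes: Sequence[GeneModel],
    cpg_islands: Sequence[GenomicInterval] = (),
    promoter_width: int = 2000,
    shore_bp: int = 2000,
    shelf_bp: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> RegionCatalog:
    """Build the full region taxonomy for a gene set.

    Per gene: whole gene, promoter (2 kb TSS-centered), strand-aware 1-5 kb
    upstream block, each exon, each intron (exon gaps), UTRs when the gene
    model carries them. CpG shores flank islands by ``shore_bp``; shelves
    flank shores by ``shelf_bp``; ``cpg_inter`` (open sea) is the complement
    and carries no owning gene — it requires ``chrom_sizes``.
    """
    cat = RegionCatalog()
    for g in genes:
        cat.add(g.gene_id, "whole_gene", g.span)
        prom = make_promoters([g], promoter_width)[0]
        cat.add(g.gene_id, "promoter", prom)
        up = _upstream_block(g)
        if up is not None:
            cat.add(g.gene_id, "upstream_1to5kb", up)
        for ex in g.exons:
            cat.add(g.gene_id, "exon", ex)
        for intr in g.introns():
            cat.add(g.gene_id, "intron", intr)
        for u in g.utr5:
            cat.add(g.gene_id, "utr5", u)
        for u in g.utr3:
            cat.add(g.gene_id, "utr3", u)

    islands = merge_intervals(cpg_islands)
    shores_raw = []
    for isl in islands:
        lo = max(0, isl.start - shore_bp)
        if lo < isl.start:
            shores_raw.append(GenomicInterval(isl.chrom, lo, isl.start))
        shores_raw.append(GenomicInterval(isl.chrom, isl.end, isl.end + shore_bp))
    shores = subtract_intervals(shores_raw, islands)
    shelves_raw = []
    for sh in merge_intervals(shores_raw):
        lo = max(0, sh.start - shelf_bp)
        if lo < sh.start:
            shelves_raw.append(GenomicInterval(sh.chrom, lo, sh.start))
        shelves_raw.append(GenomicInterval(sh.chrom, sh.end, sh.end + shelf_bp))
    shelves = subtract_intervals(shelves_raw, list(islands) + shores_raw)

    def owner(iv: GenomicInterval) -> str:
        for g in genes:
            if g.span.overlaps(iv):
                return g.gene_id
        return ""

    for isl in islands:
        cat.add(owner(isl), "cpg_island", isl)
    for sh in shores:
        cat.add(owner(sh), "cpg_shore", sh)
    for sf in shelves:
        cat.add(owner(sf), "cpg_shelf", sf)

    if chrom_sizes:
        genome = [
            GenomicInterval(c, 0, size) for c, size in sorted(chrom_sizes.items())
        ]
        covered = list(islands) + shores + shelves
        for iv in subtract_intervals(genome, covered):
            cat.add("", "cpg_inter", iv)
    return cat


def overlap_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (index_a, index_b) pairs sharing >= 1 base, half-open semantics.

    Sweep over position-sorted lists; output sorted by (index_a, index_b).
    """
    order_b = sorted(range(len(b)), key=lambda j: (b[j].chrom, b[j].start, b[j].end))
    pairs: list[tuple[int, int]] = []
    # per-chromosome active-window sweep keeps this near O((n+m) log + k)
    by_chrom: dict[str, list[int]] = {}
    for j in order_b:
        by_chrom.setdefault(b[j].chrom, []).append(j)
    for i, iv in enumerate(a):
        for j in by_chrom.get(iv.chrom, ()):
            jb = b[j]
            if jb.start >= iv.end:
                break
            if jb.end > iv.start:
                pairs.append((i, j))
    pairs.sort()
    return pairs
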