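"""Genomic-feature annotation of differentially methylated regions.

Three annotation families are supported, mirroring how MeDIP hit regions
are usually characterised:

* **CpG context** — islands, shores (0-2 kb island flanks), shelves
  (2-4 kb flanks) and open sea (everything else).  The four sets form an
  exact partition of the genome.
* **Gene features** — promoter ([TSS-1 kb, TSS), strand-aware), the 1-5 kb
  upstream window, exons, introns (gene body minus exons), 5'/3' UTRs, and
  intergenic as the fallback when nothing else is hit.
* **Repeat classes** — LINE / SINE / LTR / other, with "none" for regions
  outside any annotated repeat.

A 300-bp region can straddle annotation boundaries, so classifiers return
*every* category overlapped by >= 1 bp.  Distribution percentages use the
total number of (region, category) assignments as the denominator — the
only convention under which multi-category regions still yield bars summing
to 100% within a family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome import (
    GenomeLayout,
    GInterval,
    complement_intervals,
    merge_intervals,
    subtract_intervals,
)

__all__ = [
    "GeneModel",
    "AnnotationDB",
    "CpGContext",
    "derive_cpg_context",
    "classify_cpg",
    "classify_gene_feature",
    "classify_repeat",
    "feature_distribution",
    "REPEAT_CLASSES",
    "GENE_FEATURES",
    "CPG_FEATURES",
]

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "other")
CPG_FEATURES = ("island", "shore", "shelf", "open_sea")
GENE_FEATURES = ("promoter", "upstream_1to5kb", "exon", "intron", "utr5", "utr3", "intergenic")

PROMOTER_BP = 1_000
UPSTREAM_FAR_BP = 5_000
SHORE_BP = 2_000
SHELF_BP = 4_000


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: strand-oriented body with exon and UTR blocks."""

    name: str
    chrom: str
    strand: str
    start: int  # body start (0-based)
    end: int  # body end (exclusive)
    exons: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"empty gene body for {self.name}")
        body = [(self.start, self.end)]
        for blocks, label in ((self.exons, "exon"), (self.utr5, "utr5"), (self.utr3, "utr3")):
            for s, e in blocks:
                if not (self.start <= s < e <= self.end):
                    raise ValueError(f"{label} block ({s},{e}) outside body of {self.name}")
        exon_union = merge_intervals(self.exons) if self.exons else []
        for blocks, label in ((self.utr5, "utr5"), (self.utr3, "utr3")):
            for s, e in blocks:
                if subtract_intervals([(s, e)], exon_union):
                    raise ValueError(f"{label} block ({s},{e}) of {self.name} not inside exons")

    @property
    def tss(self) -> int:
        """First transcribed base: body start on '+', last base on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def body(self) -> GInterval:
        return GInterval(self.chrom, self.start, self.end, name=self.name)

    def introns(self) -> list[tuple[int, int]]:
        return subtract_intervals([(self.start, self.end)], self.exons)

    def promoter(self, layout: GenomeLayout) -> tuple[int, int] | None:
        """[TSS-1 kb, TSS) in transcription orientation, clipped to the
        chromosome; None when fully off-chromosome."""
        if self.strand == "+":
            s, e = self.start - PROMOTER_BP, self.start
        else:
            s, e = self.end, self.end + PROMOTER_BP
        s = max(s, 0)
        e = min(e, layout.length(self.chrom))
        return (s, e) if s < e else None

    def upstream_1to5kb(self, layout: GenomeLayout) -> tuple[int, int] | None:
        if self.strand == "+":
            s, e = self.start - UPSTREAM_FAR_BP, self.start - PROMOTER_BP
        else:
            s, e = self.end + PROMOTER_BP, self.end + UPSTREAM_FAR_BP
        s = max(s, 0)
        e = min(e, layout.length(self.chrom))
        return (s, e) if s < e else None


@dataclass
class AnnotationDB:
    """Bundle of annotation tracks on one genome layout."""

    layout: GenomeLayout
    cpg_islands: list[GInterval] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    repeats: list[GInterval] = field(default_factory=list)  # class in .name
    blacklist: list[GInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for iv in [*self.cpg_islands, *self.repeats, *self.blacklist]:
            iv.validate(self.layout)
        for rep in self.repeats:
            if rep.name not in REPEAT_CLASSES:
                raise ValueError(f"unknown repeat class {rep.name!r}")
        for gene in self.genes:
            gene.body.validate(self.layout)

    def gene_bodies(self) -> list[GInterval]:
        return [g.body for g in self.genes]


# ---------------------------------------------------------------------------
# CpG context


@dataclass
class CpGContext:
    """Partition of the genome into island / shore / shelf / open-sea sets,
    stored per chromosome as sorted disjoint (start, end) lists."""

    layout: GenomeLayout
    sets: dict[str, dict[str, list[tuple[int, int]]]]

    def intervals(self, category: str) -> list[GInterval]:
        out = []
        for chrom in self.layout.names:
            for s, e in self.sets[chrom][category]:
                out.append(GInterval(chrom, s, e, name=category))
        return out


def derive_cpg_context(
    islands: Sequence[GInterval],
    layout: GenomeLayout,
    shore_bp: int = SHORE_BP,
    shelf_bp: int = SHELF_BP,
) -> CpGContext:
    """Partition the genome around CpG islands.

    Shores are the 0-`shore_bp` flanks of (merged) islands minus the islands
    themselves; shelves the `shore_bp`-`shelf_bp` flanks minus islands and
    shores; open sea is the complement.
    """
    for iv in islands:
        iv.validate(layout)
    sets: dict[str, dict[str, list[tuple[int, int]]]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.names}
    for iv in islands:
        by_chrom[iv.chrom].append((iv.start, iv.end))
    for chrom, length in layout.chromosomes:
        isl = merge_intervals(by_chrom[chrom]) if by_chrom[chrom] else []
        near = merge_intervals(
            [(max(0, s - shore_bp), min(length, e + shore_bp)) for s, e in isl]
        ) if isl else []
        far = merge_intervals(
            [(max(0, s - shelf_bp), min(length, e + shelf_bp)) for s, e in isl]
        ) if isl else []
        shores = subtract_intervals(near, isl)
        shelves = subtract_intervals(far, near)
        open_sea = complement_intervals(far, length)
        sets[chrom] = {
            "island": isl,
            "shore": shores,
            "shelf": shelves,
            "open_sea": open_sea,
        }
    return CpGContext(layout=layout, sets=sets)


def _hits(region: GInterval, blocks: Iterable[tuple[int, int]]) -> bool:
    return any(region.start < e and s < region.end for s, e in blocks)


def classify_cpg(region: GInterval, context: CpGContext) -> set[str]:
    """All CpG-context categories the region overlaps by >= 1 bp."""
    region.validate(context.layout)
    chrom_sets = context.sets[region.chrom]
    return {cat for cat in CPG_FEATURES if _hits(region, chrom_sets[cat])}


# ---------------------------------------------------------------------------
# Gene features


def classify_gene_feature(
    region: GInterval, genes: Sequence[GeneModel], layout: GenomeLayout
) -> set[str]:
    """All gene-feature categories the region overlaps; {'intergenic'} when
    no gene-linked feature (including upstream windows) is hit."""
    region.validate(layout)
    hit: set[str] = set()
    for gene in genes:
        if gene.chrom != region.chrom:
            continue
        prom = gene.promoter(layout)
        if prom is not None and _hits(region, [prom]):
            hit.add("promoter")
        up = gene.upstream_1to5kb(layout)
        if up is not None and _hits(region, [up]):
            hit.add("upstream_1to5kb")
        if region.start < gene.end and gene.start < region.end:
            if _hits(region, gene.exons):
                hit.add("exon")
            if _hits(region, gene.introns()):
                hit.add("intron")
            if _hits(region, gene.utr5):
                hit.add("utr5")
            if _hits(region, gene.utr3):
                hit.add("utr3")
    return hit if hit else {"intergenic"}


def gene_feature_tracks(
    genes: Sequence[GeneModel], layout: GenomeLayout
) -> dict[str, list[GInterval]]:
    """Interval tracks for each gene-feature category (intergenic excluded),
    e.g. as permutation-enrichment feature sets."""
    tracks: dict[str, list[GInterval]] = {
        "promoter": [], "upstream_1to5kb": [], "exon": [], "intron": [], "utr5": [], "utr3": []
    }
    for g in genes:
        prom = g.promoter(layout)
        if prom is not None:
            tracks["promoter"].append(GInterval(g.chrom, *prom, name=g.name))
        up = g.upstream_1to5kb(layout)
        if up is not None:
            tracks["upstream_1to5kb"].append(GInterval(g.chrom, *up, name=g.name))
        for s, e in g.exons:
            tracks["exon"].append(GInterval(g.chrom, s, e, name=g.name))
        for s, e in g.introns():
            tracks["intron"].append(GInterval(g.chrom, s, e, name=g.name))
        for s, e in g.utr5:
            tracks["utr5"].append(GInterval(g.chrom, s, e, name=g.name))
        for s, e in g.utr3:
            tracks["utr3"].append(GInterval(g.chrom, s, e, name=g.name))
    return tracks


# ---------------------------------------------------------------------------
# Repeats


def build_repeat_index(repeats: Sequence[GInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for rep in repeats:
        if rep.name not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {rep.name!r}")
        trees.setdefault(rep.chrom, IntervalTree()).addi(rep.start, rep.end, rep.name)
    return trees


def classify_repeat(
    region: GInterval,
    repeats: Sequence[GInterval] | dict[str, IntervalTree],
) -> set[str]:
    """Repeat classes the region overlaps; {'none'} outside all repeats."""
    index = repeats if isinstance(repeats, dict) else build_repeat_index(repeats)
    tree = index.get(region.chrom)
    if tree is None:
        return {"none"}
    classes = {hit.data for hit in tree.overlap(region.start, region.end)}
    return classes if classes else {"none"}


# ---------------------------------------------------------------------------
# Distributions


def feature_distribution(
    regions: Sequence[GInterval],
    classifier: Callable[[GInterval], Iterable[str]],
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Count (region, category) assignments and express them as percentages.

    Each region contributes one assignment per category it hits, so
    multi-category regions appear in several bars; the percentages over all
    assignments sum to 100 within the family.
    """
    if not regions:
        raise ValueError("feature_distribution requires at least one region")
    counts: dict[str, int] = {}
    for region in regions:
        for cat in classifier(region):
            counts[cat] = counts.get(cat, 0) + 1
    total = sum(counts.values())
    order = list(categories) if categories is not None else sorted(counts)
    rows = [
        {
            "category": cat,
            "count": counts.get(cat, 0),
            "percentage": 100.0 * counts.get(cat, 0) / total,
        }
        for cat in order
    ]
    extra = [c for c in counts if categories is not None and c not in order]
    for cat in sorted(extra):
        rows.append(
            {"category": cat, "count": counts[cat], "percentage": 100.0 * counts[cat] / total}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene-model I/O (minimal GFF-like TSV; block lists as "s-e,s-e")


def _blocks_to_text(blocks: Iterable[tuple[int, int]]) -> str:
    text = ",".join(f"{s}-{e}" for s, e in blocks)
    return text if text else "."


def _blocks_from_text(text: str) -> tuple[tuple[int, int], ...]:
    if text in {".", ""}:
        return ()
    out = []
    for part in text.split(","):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchrom\tstrand\tstart\tend\texons\tutr5\tutr3\n")
        for g in genes:
            fh.write(
                f"{g.name}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\t"
                f"{_blocks_to_text(g.exons)}\t{_blocks_to_text(g.utr5)}\t{_blocks_to_text(g.utr3)}\n"
            )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    genes = []
    for row in frame.itertuples():
        genes.append(
            GeneModel(
                name=row.gene,
                chrom=row.chrom,
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                exons=_blocks_from_text(row.exons),
                utr5=_blocks_from_text(row.utr5),
                utr3=_blocks_from_text(row.utr3),
            )
        )
    return genes
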