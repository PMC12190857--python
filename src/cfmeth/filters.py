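"""Bin-count construction and the four-stage bin filtering cascade.

cfMeDIP-seq fragments are aggregated into fixed-width genome bins (each
fragment counted once, into the bin containing its midpoint).  Before
differential testing, bins pass through four filters, in this order:

1. **blacklist** — any bin overlapping a problematic-region blacklist
   interval by >= 1 bp is removed;
2. **pbl_background** — bins with more than `pbl_threshold` (default 20,
   strict) reads in at least one peripheral-blood-leukocyte sample are
   removed: high leukocyte signal marks hematopoietic background rather
   than tumour-derived methylation;
3. **low_total** — bins whose summed count over all plasma (cfDNA) samples
   is below `min_total` (default 10, strict) are removed as noise;
4. **no_cpg** — bins containing no CpG dinucleotide cannot carry a genuine
   methylation signal and are removed.

The cascade is idempotent and order-sensitive (the report records per-stage
removals against the bins still alive when the stage runs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import BinGrid, GInterval

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "FilterReport",
    "count_fragments",
    "blacklist_filter",
    "pbl_background_filter",
    "low_total_filter",
    "cpg_presence_filter",
    "run_filter_cascade",
    "CFDNA_GROUPS",
]

CFDNA_GROUPS = ("OC", "benign", "healthy")
ALL_GROUPS = CFDNA_GROUPS + ("PBL",)


@dataclass
class CountMatrix:
    """Non-negative integer bin x sample counts bound to a bin grid.

    ``counts`` is a DataFrame indexed by global bin id with one column per
    sample.  Rows may be a subset of the grid (e.g. after filtering).
    """

    grid: BinGrid
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample columns")
        idx = self.counts.index
        if len(idx) and (idx.min() < 0 or idx.max() >= self.grid.n_bins):
            raise ValueError("count rows reference bins outside the grid")
        vals = self.counts.to_numpy()
        if vals.size and ((vals < 0).any() or not np.issubdtype(vals.dtype, np.integer)):
            raise ValueError("counts must be non-negative integers")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def restrict_bins(self, bin_ids: Sequence[int]) -> "CountMatrix":
        return CountMatrix(self.grid, self.counts.loc[sorted(bin_ids)])

    def restrict_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.grid, self.counts[list(sample_ids)])

    def to_tsv(self, path: str | Path) -> None:
        frame = self.grid.to_frame().loc[self.counts.index]
        out = pd.concat([frame, self.counts], axis=1)
        out.to_csv(path, sep="\t", index_label="bin_id")

    @classmethod
    def from_tsv(cls, path: str | Path, grid: BinGrid) -> "CountMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="bin_id")
        counts = frame.drop(columns=["chrom", "start", "end"])
        return cls(grid, counts.astype(np.int64))


@dataclass
class SampleSheet:
    """Sample metadata: id, diagnostic group, library batch."""

    table: pd.DataFrame  # columns: sample_id, group, batch

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "batch"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in sheet")
        bad = set(self.table["group"]) - set(ALL_GROUPS)
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")

    def ids(self, *groups: str) -> list[str]:
        if not groups:
            return list(self.table["sample_id"])
        return list(self.table.loc[self.table["group"].isin(groups), "sample_id"])

    def group_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id, "group"]
        if row.empty:
            raise KeyError(f"unknown sample {sample_id!r}")
        return str(row.iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, dtype={"sample_id": str, "group": str, "batch": str}))


@dataclass
class FilterReport:
    """Per-stage removal accounting for the filtering cascade."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)  # (name, removed, remaining)
    survivors: set[int] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, removed: int, remaining: int) -> None:
        self.stages.append((name, removed, remaining))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "bins_removed", "bins_remaining"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Counting


def count_fragments(fragments: Sequence[GInterval], grid: BinGrid) -> np.ndarray:
    """Count fragments into bins by midpoint; returns a full-grid column.

    Each fragment is counted exactly once, into the bin containing
    floor((start + end) / 2); column total equals the number of fragments.
    """
    col = np.zeros(grid.n_bins, dtype=np.int64)
    for i, frag in enumerate(fragments):
        try:
            frag.validate(grid.layout)
            mid = (frag.start + frag.end) // 2
            col[grid.bin_of(frag.chrom, mid)] += 1
        except (ValueError, KeyError) as exc:
            raise ValueError(f"fragment record {i}: {exc}") from exc
    return col


def counts_from_fragments(
    fragments_by_sample: dict[str, Sequence[GInterval]], grid: BinGrid
) -> CountMatrix:
    cols = {s: count_fragments(frags, grid) for s, frags in fragments_by_sample.items()}
    frame = pd.DataFrame(cols)
    frame.index.name = "bin_id"
    return CountMatrix(grid, frame)


# ---------------------------------------------------------------------------
# Individual filter stages (each returns the set of bin ids it removes,
# evaluated over the bins present in its input)


def blacklist_filter(grid: BinGrid, blacklist: Sequence[GInterval]) -> set[int]:
    """Bins overlapping any blacklist interval by >= 1 bp."""
    removed: set[int] = set()
    for iv in blacklist:
        removed.update(grid.overlapping_bins(iv))
    return removed


def pbl_background_filter(pbl_counts: pd.DataFrame, threshold: int = 20) -> set[int]:
    """Bins exceeding the leukocyte background threshold (strict >) in at
    least one PBL sample."""
    if pbl_counts.shape[1] == 0:
        raise ValueError("pbl_background_filter requires >= 1 PBL sample")
    mask = (pbl_counts > threshold).any(axis=1)
    return set(pbl_counts.index[mask])


def low_total_filter(cfdna_counts: pd.DataFrame, min_total: int = 10) -> set[int]:
    """Bins whose total count over all plasma samples is below `min_total`
    (strict <)."""
    if cfdna_counts.shape[1] == 0:
        raise ValueError("low_total_filter requires >= 1 cfDNA sample")
    totals = cfdna_counts.sum(axis=1)
    return set(cfdna_counts.index[totals < min_total])


def cpg_presence_filter(grid: BinGrid, cpg_counts: np.ndarray) -> set[int]:
    """Bins with zero CpG dinucleotides (cannot carry methylation signal)."""
    if len(cpg_counts) != grid.n_bins:
        raise ValueError(
            f"cpg_counts length {len(cpg_counts)} does not match grid ({grid.n_bins} bins)"
        )
    return set(np.nonzero(np.asarray(cpg_counts) == 0)[0].tolist())


# ---------------------------------------------------------------------------
# Cascade


def run_filter_cascade(
    counts: CountMatrix,
    sheet: SampleSheet,
    blacklist: Sequence[GInterval],
    cpg_counts: np.ndarray,
    pbl_counts: pd.DataFrame | None = None,
    pbl_threshold: int = 20,
    min_total: int = 10,
) -> tuple[CountMatrix, FilterReport]:
    """Apply blacklist -> PBL background -> low-total -> no-CpG, in order.

    PBL counts may live in `counts` itself (columns with group PBL on the
    sheet) or be passed separately (external leukocyte reference).  The
    returned matrix is restricted to plasma (OC/benign/healthy) samples and
    surviving bins.
    """
    report = FilterReport()
    cfdna_ids = [s for s in counts.samples if sheet.group_of(s) in CFDNA_GROUPS]
    if not cfdna_ids:
        raise ValueError("no cfDNA (OC/benign/healthy) samples in count matrix")
    if pbl_counts is None:
        pbl_ids = [s for s in counts.samples if sheet.group_of(s) == "PBL"]
        pbl_counts = counts.counts[pbl_ids]

    alive = set(counts.counts.index)

    removed = blacklist_filter(counts.grid, blacklist) & alive
    alive -= removed
    report.add_stage("blacklist", len(removed), len(alive))

    if pbl_counts.shape[1] == 0:
        report.warnings.append("no PBL samples: background stage skipped")
        report.add_stage("pbl_background", 0, len(alive))
    else:
        removed = pbl_background_filter(pbl_counts.loc[sorted(alive)], pbl_threshold)
        alive -= removed
        report.add_stage("pbl_background", len(removed), len(alive))

    cf = counts.counts.loc[sorted(alive), cfdna_ids]
    removed = low_total_filter(cf, min_total)
    alive -= removed
    report.add_stage("low_total", len(removed), len(alive))

    removed = cpg_presence_filter(counts.grid, cpg_counts) & alive
    alive -= removed
    report.add_stage("no_cpg", len(removed), len(alive))

    report.survivors = set(alive)
    filtered = CountMatrix(counts.grid, counts.counts.loc[sorted(alive), cfdna_ids])
    return filtered, report
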