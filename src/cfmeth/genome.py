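"""Genome coordinate system, interval arithmetic, binning, and BED/FASTA I/O.

Every stage of the analysis shares one coordinate convention: 0-based,
half-open intervals internally (BED-compatible), with 1-based inclusive
coordinates only at report boundaries.  A :class:`BinGrid` tiles every
chromosome with fixed-width non-overlapping bins (default 300 bp, the
resolution at which cfMeDIP-seq fragment counts are aggregated); the last
bin of a chromosome is kept even when truncated so that the tiling is
complete.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "GInterval",
    "BinGrid",
    "build_bin_grid",
    "from_one_based",
    "to_one_based",
    "overlaps",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_fasta",
    "write_fasta",
    "count_cpg",
    "merge_intervals",
    "subtract_intervals",
    "complement_intervals",
    "intersect_len",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths; defines serialization order."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome layout must contain at least one chromosome")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_dict(cls, sizes: dict[str, int] | Sequence[tuple[str, int]]) -> "GenomeLayout":
        items = sizes.items() if isinstance(sizes, dict) else sizes
        return cls(tuple((str(n), int(l)) for n, l in items))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def chrom_order(self, chrom: str) -> int:
        return self.names.index(chrom)


@dataclass(frozen=True, order=True)
class GInterval:
    """Genomic interval, 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def validate(self, layout: GenomeLayout) -> "GInterval":
        if self.chrom not in layout:
            raise ValueError(f"chromosome {self.chrom!r} not in layout")
        if self.end > layout.length(self.chrom):
            raise ValueError(
                f"interval [{self.start}, {self.end}) exceeds {self.chrom} "
                f"length {layout.length(self.chrom)}"
            )
        return self


def from_one_based(chrom: str, start_1: int, stop_1: int, name: str | None = None) -> GInterval:
    """Convert 1-based inclusive coordinates (as printed in report tables)
    to an internal half-open interval. Width = stop_1 - start_1 + 1."""
    if start_1 < 1:
        raise ValueError(f"1-based start must be >= 1, got {start_1}")
    if stop_1 < start_1:
        raise ValueError(f"stop {stop_1} precedes start {start_1}")
    return GInterval(chrom, start_1 - 1, stop_1, name=name)


def to_one_based(iv: GInterval) -> tuple[str, int, int]:
    """Inverse of :func:`from_one_based`: (chrom, start_1, stop_1) inclusive."""
    return iv.chrom, iv.start + 1, iv.end


def overlaps(a: GInterval, b: GInterval) -> bool:
    """True iff the two intervals share at least one base pair."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


class BinGrid:
    """Fixed-width non-overlapping tiling of a genome.

    Global bin indices run over chromosomes in layout order; index <->
    (chrom, start) is a bijection.  The final bin of each chromosome is
    truncated at the chromosome end when the length is not a multiple of
    the bin width.
    """

    def __init__(self, layout: GenomeLayout, width: int = 300):
        if width < 1:
            raise ValueError(f"bin width must be >= 1, got {width}")
        self.layout = layout
        self.width = int(width)
        self._nbins = {
            name: -(-length // self.width) for name, length in layout.chromosomes
        }
        self._offsets: dict[str, int] = {}
        acc = 0
        for name, _ in layout.chromosomes:
            self._offsets[name] = acc
            acc += self._nbins[name]
        self._total = acc

    @property
    def n_bins(self) -> int:
        return self._total

    def bins_on(self, chrom: str) -> int:
        return self._nbins[chrom]

    def bin_interval(self, index: int) -> GInterval:
        if not 0 <= index < self._total:
            raise IndexError(f"bin index {index} out of range [0, {self._total})")
        for name, length in self.layout.chromosomes:
            if index < self._nbins[name]:
                start = index * self.width
                return GInterval(name, start, min(start + self.width, length))
            index -= self._nbins[name]
        raise AssertionError("unreachable")

    def bin_index(self, chrom: str, start: int) -> int:
        """Global index of the bin whose start coordinate is `start`."""
        idx = self.bin_of(chrom, start)
        if self.bin_interval(idx).start != start:
            raise ValueError(f"{start} is not a bin start on {chrom}")
        return idx

    def bin_of(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing base `pos`."""
        if chrom not in self.layout:
            raise ValueError(f"chromosome {chrom!r} not in layout")
        if not 0 <= pos < self.layout.length(chrom):
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offsets[chrom] + pos // self.width

    def overlapping_bins(self, iv: GInterval) -> range:
        """Global indices of all bins overlapping the interval (>= 1 bp)."""
        iv.validate(self.layout)
        first = iv.start // self.width
        last = (iv.end - 1) // self.width
        off = self._offsets[iv.chrom]
        return range(off + first, off + last + 1)

    def __iter__(self) -> Iterator[GInterval]:
        for i in range(self._total):
            yield self.bin_interval(i)

    def to_frame(self):
        """Bin table as a DataFrame (bin_id index; chrom, start, end)."""
        import pandas as pd

        rows = []
        for name, length in self.layout.chromosomes:
            starts = np.arange(self._nbins[name]) * self.width
            ends = np.minimum(starts + self.width, length)
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        frame = pd.concat(rows, ignore_index=True)
        frame.index.name = "bin_id"
        return frame


def build_bin_grid(layout: GenomeLayout, width: int = 300) -> BinGrid:
    """Tile every chromosome with `width`-bp non-overlapping bins."""
    return BinGrid(layout, width)


# ---------------------------------------------------------------------------
# Sequence utilities


def count_cpg(sequence: str) -> int:
    """Number of CpG dinucleotides on the forward strand.

    CpG is its own reverse complement, so forward-strand counting covers
    both strands.  Overlap-free by construction ("CGCG" -> 2; scanning at
    step 1 finds CG at positions 0 and 2).
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.count("CG")


# ---------------------------------------------------------------------------
# Interval-set arithmetic on (start, end) tuples, half-open.
# These primitives underpin CpG-context derivation (shores/shelves/open sea)
# and intron construction; they are property-tested against a per-bp oracle.


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list.

    Adjacent intervals ([0,5),[5,9)) are coalesced.
    """
    ivs = sorted(ivs)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(
    a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference a \\ b of half-open interval unions."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def complement_intervals(a: Iterable[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    """Complement of an interval union within [0, length)."""
    return subtract_intervals([(0, length)], a)


def intersect_len(a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]) -> int:
    """Total overlap in bp between two interval unions."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


# ---------------------------------------------------------------------------
# File I/O


def read_bed(path: str | Path, layout: GenomeLayout | None = None) -> list[GInterval]:
    """Read a BED3/BED6 file (0-based half-open) into intervals.

    Malformed lines raise with the 1-based line number; with a layout,
    unknown chromosomes and out-of-bounds records are rejected the same way.
    """
    out: list[GInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            try:
                iv = GInterval(chrom, start, end, name=name)
                if layout is not None:
                    iv.validate(layout)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Two-column TSV (name, length) -> layout, preserving file order."""
    pairs: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
            pairs.append((fields[0], int(fields[1])))
    return GenomeLayout(tuple(pairs))


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {name: sequence} via Biopython."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def cpg_per_bin(grid: BinGrid, sequences: dict[str, str]) -> np.ndarray:
    """CpG dinucleotide count for every bin of the grid.

    A CpG straddling a bin boundary is credited to the bin containing the C.
    """
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    for name, length in grid.layout.chromosomes:
        if name not in sequences:
            raise ValueError(f"no sequence provided for chromosome {name!r}")
        seq = sequences[name].upper()
        if len(seq) != length:
            raise ValueError(
                f"sequence length {len(seq)} for {name!r} disagrees with layout {length}"
            )
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = arr[:-1] == ord("C")
        is_g = arr[1:] == ord("G")
        cpg_pos = np.nonzero(is_c & is_g)[0]  # position of the C
        off = grid._offsets[name]
        np.add.at(counts, off + cpg_pos // grid.width, 1)
    return counts
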