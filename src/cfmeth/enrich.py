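"""Permutation-based genomic-feature enrichment and gene-set ORA.

**Permutation Z-scores.** To ask whether a region set (e.g. the
hypermethylated DMRs) overlaps a feature track more than chance expects,
each region is redistributed uniformly at random while preserving its
length and chromosome; over ``n`` such randomizations the number of
regions overlapping the feature set (each region counted at most once,
>= 1 bp overlap) forms the null distribution, and
``Z = (observed - null mean) / null SD`` (SD with denominator n-1).
|Z| > 2 is read as strong evidence of enrichment (positive) or depletion
(negative).  Randomized regions may overlap each other, and land anywhere
on their chromosome unless an explicit mask is supplied.

**Over-representation analysis.** Gene-set enrichment of a query gene list
against a GMT database via the hypergeometric upper tail
``P(X >= k)`` with universe size N, term size K, query size n and overlap
k; BH adjustment and a Storey q-value (lambda = 0.5, falling back to BH
weighting when the pi0 estimate is degenerate); a term is significant when
both padj and q fall below 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import bh_adjust
from .genome import GenomeLayout, GInterval, merge_intervals, subtract_intervals

__all__ = [
    "PermResult",
    "randomize_regions",
    "count_region_overlaps",
    "permutation_z",
    "hypergeom_ora",
    "storey_qvalue",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class PermResult:
    feature: str
    observed: int
    null_mean: float
    null_sd: float
    z: float
    n_permutations: int
    seed: int | None
    verdict: str  # enriched / depleted / none / undefined

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# Randomization


def _region_space(
    region: GInterval, layout: GenomeLayout, mask: Mapping[str, list[tuple[int, int]]] | None
) -> list[tuple[int, int]]:
    """Admissible start positions [lo, hi) for a region on its chromosome."""
    L = layout.length(region.chrom)
    width = len(region)
    if width > L:
        raise ValueError(
            f"region of length {width} does not fit chromosome {region.chrom} ({L} bp)"
        )
    if mask is None or region.chrom not in mask:
        return [(0, L - width + 1)]
    # placements must avoid masked intervals entirely
    allowed = subtract_intervals([(0, L)], mask[region.chrom])
    spaces = [(s, e - width + 1) for s, e in allowed if e - s >= width]
    if not spaces:
        raise ValueError(f"mask leaves no room for a {width}-bp region on {region.chrom}")
    return spaces


def randomize_regions(
    regions: Sequence[GInterval],
    layout: GenomeLayout,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    mask: Mapping[str, list[tuple[int, int]]] | None = None,
) -> list[GInterval]:
    """Uniformly replace each region on its own chromosome, keeping length.

    Placements are independent; randomized regions may overlap each other.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for region in regions:
        spaces = _region_space(region, layout, mask)
        sizes = np.array([hi - lo for lo, hi in spaces], dtype=float)
        which = int(rng.choice(len(spaces), p=sizes / sizes.sum())) if len(spaces) > 1 else 0
        lo, hi = spaces[which]
        start = int(rng.integers(lo, hi))
        out.append(GInterval(region.chrom, start, start + len(region), name=region.name))
    return out


# ---------------------------------------------------------------------------
# Overlap counting


def _merged_by_chrom(features: Sequence[GInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        by.setdefault(f.chrom, []).append((f.start, f.end))
    out = {}
    for chrom, ivs in by.items():
        merged = merge_intervals(ivs)
        out[chrom] = (
            np.array([s for s, _ in merged], dtype=np.int64),
            np.array([e for _, e in merged], dtype=np.int64),
        )
    return out


def _overlap_mask(
    starts: np.ndarray, ends: np.ndarray, fs: np.ndarray, fe: np.ndarray
) -> np.ndarray:
    """For queries [starts, ends) against merged sorted features (fs, fe):
    True where the query overlaps >= 1 feature bp."""
    idx = np.searchsorted(fs, ends, side="left")  # features with start < end
    prev_end = np.where(idx > 0, fe[np.maximum(idx - 1, 0)], np.iinfo(np.int64).min)
    return (idx > 0) & (prev_end > starts)


def count_region_overlaps(
    regions: Sequence[GInterval], features: Sequence[GInterval]
) -> int:
    """Number of regions overlapping >= 1 feature by >= 1 bp (each region
    counted at most once)."""
    merged = _merged_by_chrom(features)
    count = 0
    for region in regions:
        if region.chrom not in merged:
            continue
        fs, fe = merged[region.chrom]
        if _overlap_mask(
            np.array([region.start]), np.array([region.end]), fs, fe
        )[0]:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Permutation Z


def permutation_z(
    regions: Sequence[GInterval],
    features: Sequence[GInterval],
    layout: GenomeLayout,
    n: int = 1000,
    seed: int | None = None,
    feature_name: str = "feature",
    mask: Mapping[str, list[tuple[int, int]]] | None = None,
) -> PermResult:
    """Observed-vs-null overlap Z-score over `n` random redistributions.

    The uniform-placement null is evaluated vectorized: all `n` placements
    of every region are drawn at once and checked against the merged
    feature set, matching :func:`count_region_overlaps` semantics exactly.
    """
    if not regions:
        raise ValueError("permutation_z requires a non-empty region list")
    if n < 2:
        raise ValueError("need n >= 2 permutations for a sample SD")
    rng = np.random.default_rng(seed)
    merged = _merged_by_chrom(features)
    observed = count_region_overlaps(regions, features)

    null_counts = np.zeros(n, dtype=np.int64)
    for region in regions:
        spaces = _region_space(region, layout, mask)
        width = len(region)
        sizes = np.array([hi - lo for lo, hi in spaces], dtype=np.int64)
        if len(spaces) == 1:
            starts = rng.integers(spaces[0][0], spaces[0][1], size=n)
        else:
            pick = rng.choice(len(spaces), size=n, p=sizes / sizes.sum())
            starts = np.empty(n, dtype=np.int64)
            for i, (lo, hi) in enumerate(spaces):
                sel = pick == i
                starts[sel] = rng.integers(lo, hi, size=int(sel.sum()))
        if region.chrom in merged:
            fs, fe = merged[region.chrom]
            null_counts += _overlap_mask(starts, starts + width, fs, fe)

    null_mean = float(null_counts.mean())
    null_sd = float(null_counts.std(ddof=1))
    if null_sd == 0.0:
        return PermResult(feature_name, observed, null_mean, 0.0, float("nan"), n, seed, "undefined")
    z = (observed - null_mean) / null_sd
    verdict = "enriched" if z > 2 else "depleted" if z < -2 else "none"
    return PermResult(feature_name, observed, null_mean, null_sd, z, n, seed, verdict)


# ---------------------------------------------------------------------------
# Over-representation analysis


def storey_qvalue(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with fixed lambda; BH fallback when pi0 degenerates."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    pi0 = np.sum(p > lam) / (m * (1.0 - lam))
    if not (0.0 < pi0 <= 1.0):
        pi0 = 1.0
    return np.minimum(pi0 * bh_adjust(p), 1.0)


def hypergeom_ora(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each gene set.

    Terms are intersected with the universe before testing; the query is
    likewise restricted to the universe (its in-universe size is the
    GeneRatio denominator).  A term is significant iff padj < alpha AND
    qvalue < alpha.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query = set(query_genes) & universe_set
    N, n = len(universe_set), len(query)
    rows = []
    for term, members in gene_sets.items():
        term_set = set(members) & universe_set
        K = len(term_set)
        if K == 0:
            continue
        hits = sorted(query & term_set)
        k = len(hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            {
                "term": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "gene_ratio": k / n if n else 0.0,
                "gene_ratio_text": f"{k}/{n}",
                "pvalue": min(p, 1.0),
                "genes": ",".join(hits) if hits else ".",
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["padj"] = bh_adjust(table["pvalue"].to_numpy())
    table["qvalue"] = storey_qvalue(table["pvalue"].to_numpy())
    table["significant"] = (table["padj"] < alpha) & (table["qvalue"] < alpha)
    return table.sort_values(["pvalue", "term"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need term, description, >=1 gene")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(sets):
            genes = "\t".join(sorted(sets[term]))
            fh.write(f"{term}\tna\t{genes}\n")
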