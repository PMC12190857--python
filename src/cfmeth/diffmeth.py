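"""Negative-binomial Wald differential-methylation testing.

The count model: bin counts are NB-distributed with variance
``mu + alpha * mu^2``; each sample has a size factor absorbing sequencing
depth (median-of-ratios normalization); each bin has a dispersion ``alpha``
estimated by method of moments from within-group residuals.  For the
two-group contrast (case = ovarian cancer, reference = control) the
per-group means are fitted by Fisher-scoring maximum likelihood at fixed
dispersion with ``log(size factor)`` offsets; the Wald statistic is the
log2 fold change over its expected-information standard error, with a
two-sided normal p-value and Benjamini-Hochberg adjustment across tested
bins.  Bins with an all-zero group are flagged untested (no pseudocounts)
and excluded from the adjustment.

This is a deliberately transparent re-implementation of the standard
count-based pipeline: no fold-change shrinkage, no independent filtering,
no outlier refitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .filters import CountMatrix, SampleSheet, CFDNA_GROUPS
from .genome import BinGrid, GenomeLayout, GInterval

__all__ = [
    "size_factors",
    "estimate_dispersion",
    "wald_dmr_test",
    "bh_adjust",
    "call_dmrs",
    "map_dmrs_to_genes",
    "dmr_analysis",
    "subgroup_dmr",
    "robustness_excluding",
    "RobustSet",
    "attach_coordinates",
    "nb_loglik",
]

ALPHA_MIN = 1e-8


# ---------------------------------------------------------------------------
# Normalization


def size_factors(counts: pd.DataFrame, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference bins are those with strictly positive counts in every sample;
    with `allow_pseudo_reference` the fallback reference is bins positive
    in at least half the samples (geometric mean over positive entries).
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors require >= 2 samples")
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        ref = mat[all_pos]
        log_geo = np.log(ref).mean(axis=1)
        ratios = np.log(ref) - log_geo[:, None]
    else:
        if not allow_pseudo_reference:
            raise ValueError(
                "no bin has positive counts in every sample; rerun with "
                "allow_pseudo_reference=True to use bins positive in >= 50% of samples"
            )
        half_pos = (mat > 0).mean(axis=1) >= 0.5
        if not half_pos.any():
            raise ValueError("no usable reference bins even for pseudo-reference")
        ref = mat[half_pos]
        with np.errstate(divide="ignore"):
            logs = np.where(ref > 0, np.log(ref), np.nan)
        log_geo = np.nanmean(logs, axis=1)
        ratios = logs - log_geo[:, None]
    log_factors = np.nanmedian(ratios, axis=0)
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# Dispersion


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: pd.Series,
    alpha_min: float = ALPHA_MIN,
) -> pd.Series:
    """Method-of-moments per-bin NB dispersion from within-group residuals.

    alpha_b = max((s2_b - mean_b) / mean_b^2, alpha_min), with s2 the pooled
    within-group variance of normalized counts and mean_b their overall
    mean.  Bins with zero mean get NaN (untested downstream).
    """
    f = factors.loc[counts.columns].to_numpy(dtype=float)
    y = counts.to_numpy(dtype=float) / f[None, :]
    labels = groups.loc[counts.columns].to_numpy()
    n, g_levels = y.shape[1], np.unique(labels)
    ss = np.zeros(y.shape[0])
    for g in g_levels:
        sel = labels == g
        sub = y[:, sel]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    dof = n - len(g_levels)
    if dof < 1:
        raise ValueError("need more samples than groups for dispersion estimation")
    s2 = ss / dof
    mean = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mean) / mean**2
    alpha = np.where(mean > 0, np.maximum(alpha, alpha_min), np.nan)
    return pd.Series(alpha, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# Likelihood machinery


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Exact NB log-likelihood (var = mu + alpha mu^2) of one bin."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-12:
        return float(np.sum(stats.poisson.logpmf(y, mu)))
    r = 1.0 / alpha
    p = r / (r + mu)
    return float(np.sum(stats.nbinom.logpmf(y, r, p)))


def _fit_group_mean(
    Y: np.ndarray, f: np.ndarray, alpha: np.ndarray, max_iter: int = 100, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Fisher-scoring MLE of the group mean for every bin.

    Model: y_bs ~ NB(f_s * m_b, alpha_b).  Returns (m, info) where info is
    the expected Fisher information with respect to log(m); bins with all
    zero counts get m = 0 and info = 0.
    """
    Y = np.asarray(Y, dtype=float)
    f = np.asarray(f, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    tot = Y.sum(axis=1)
    m = tot / f.sum()
    active = tot > 0
    eta = np.where(active, np.log(np.maximum(m, 1e-300)), 0.0)
    r = 1.0 / np.maximum(alpha, ALPHA_MIN)
    for _ in range(max_iter):
        mu = f[None, :] * np.exp(eta)[:, None]
        denom = 1.0 + np.maximum(alpha, 0.0)[:, None] * mu
        score = (Y - mu * (Y * np.maximum(alpha, 0.0)[:, None] + 1.0) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.where(active & (info > 0), score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        eta = eta + step
        if np.max(np.abs(step)) < tol:
            break
    m_hat = np.where(active, np.exp(eta), 0.0)
    mu = f[None, :] * m_hat[:, None]
    info = (mu / (1.0 + np.maximum(alpha, 0.0)[:, None] * mu)).sum(axis=1)
    return m_hat, np.where(active, info, 0.0)


# ---------------------------------------------------------------------------
# Wald test


def wald_dmr_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    dispersions: pd.Series,
    condition: pd.Series,
    case: str = "OC",
    reference: str = "control",
) -> pd.DataFrame:
    """Two-group NB Wald test per bin, case vs reference.

    `condition` maps every sample column to one of exactly two labels.
    Returns a table indexed by bin id with baseMean, log2FoldChange, lfcSE,
    stat, pvalue, padj, direction and a tested flag.  log2FC > 0 means
    higher methylation signal in the case group.
    """
    cond = condition.loc[counts.columns]
    levels = set(cond.unique())
    if levels != {case, reference}:
        raise ValueError(f"condition must have exactly levels {{{case}, {reference}}}, got {levels}")
    f = factors.loc[counts.columns].to_numpy(dtype=float)
    alpha = dispersions.loc[counts.index].to_numpy(dtype=float)
    Y = counts.to_numpy(dtype=float)
    case_sel = (cond == case).to_numpy()

    tested = ~np.isnan(alpha)
    alpha_f = np.where(tested, alpha, ALPHA_MIN)

    m_case, i_case = _fit_group_mean(Y[:, case_sel], f[case_sel], alpha_f)
    m_ref, i_ref = _fit_group_mean(Y[:, ~case_sel], f[~case_sel], alpha_f)

    # a group with all zeros -> untested (no pseudocount)
    tested &= (m_case > 0) & (m_ref > 0)

    ln2 = np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(m_case / m_ref)
        se = np.sqrt(1.0 / i_case + 1.0 / i_ref) / ln2
        z = np.where(se > 0, lfc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    base_mean = (Y / f[None, :]).mean(axis=1)
    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": np.where(tested, lfc, np.nan),
            "lfcSE": np.where(tested, se, np.nan),
            "stat": np.where(tested, z, np.nan),
            "pvalue": np.where(tested, pvalue, np.nan),
            "tested": tested,
        },
        index=counts.index,
    )
    padj = np.full(len(table), np.nan)
    if tested.any():
        padj[tested] = bh_adjust(table.loc[tested, "pvalue"].to_numpy())
    table["padj"] = padj
    table["direction"] = np.select(
        [table["log2FoldChange"] > 0, table["log2FoldChange"] < 0], ["hyper", "hypo"], default=""
    )
    table.index.name = "bin_id"
    return table


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj for the i-th smallest p is min over j >= i of m * p_(j) / j,
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_dmrs(table: pd.DataFrame, alpha: float = 0.1) -> tuple[pd.DataFrame, dict[str, int]]:
    """Significant bins at padj < alpha (strict) with a direction tally.

    Bins with log2FC exactly 0 are excluded from both tallies.
    """
    called = table[table["padj"] < alpha].copy()
    tally = {
        "hyper": int((called["log2FoldChange"] > 0).sum()),
        "hypo": int((called["log2FoldChange"] < 0).sum()),
    }
    return called, tally


# ---------------------------------------------------------------------------
# Gene mapping


def map_dmrs_to_genes(
    dmrs: pd.DataFrame,
    gene_bodies: Sequence[GInterval],
    grid: BinGrid,
) -> pd.DataFrame:
    """Assign called DMRs to genes by genomic overlap.

    A gene is included iff >= 1 DMR overlaps its body by >= 1 bp.  The
    representative DMR per gene is the one with the lowest padj, ties
    broken by (chromosome order, start).  Returns a table indexed by gene
    with columns bin_id, chrom, start, end, padj, log2FoldChange.
    """
    layout = grid.layout
    trees: dict[str, IntervalTree] = {}
    for body in gene_bodies:
        if body.name is None:
            raise ValueError("gene bodies must be named")
        trees.setdefault(body.chrom, IntervalTree()).addi(body.start, body.end, body.name)

    best: dict[str, tuple[tuple[float, int, int], dict]] = {}
    for bin_id, row in dmrs.iterrows():
        iv = grid.bin_interval(int(bin_id))
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        key = (float(row["padj"]), layout.chrom_order(iv.chrom), iv.start)
        payload = {
            "bin_id": int(bin_id),
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "padj": float(row["padj"]),
            "log2FoldChange": float(row["log2FoldChange"]),
        }
        for hit in tree.overlap(iv.start, iv.end):
            gene = hit.data
            if gene not in best or key < best[gene][0]:
                best[gene] = (key, payload)
    frame = pd.DataFrame(
        {gene: payload for gene, (_, payload) in best.items()}
    ).T
    if frame.empty:
        frame = pd.DataFrame(
            columns=["bin_id", "chrom", "start", "end", "padj", "log2FoldChange"]
        )
    frame.index.name = "gene"
    return frame.sort_index()


# ---------------------------------------------------------------------------
# End-to-end contrasts


def _condition_series(sheet: SampleSheet, samples: Sequence[str], case: str) -> pd.Series:
    labels = {s: (case if sheet.group_of(s) == case else "control") for s in samples}
    return pd.Series(labels)


def dmr_analysis(
    counts: CountMatrix,
    sheet: SampleSheet,
    case: str = "OC",
    control_groups: Sequence[str] = ("benign", "healthy"),
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Normalization + dispersion + Wald test for one contrast.

    Size factors and dispersions are re-estimated on exactly the samples
    entering the contrast (so subgroup and leave-one-out analyses are full
    re-runs, not reuses of full-cohort estimates).
    """
    keep = [
        s
        for s in counts.samples
        if s not in set(exclude) and sheet.group_of(s) in {case, *control_groups}
    ]
    case_n = sum(sheet.group_of(s) == case for s in keep)
    if case_n == 0 or case_n == len(keep):
        raise ValueError("contrast requires non-empty case and control groups")
    sub = counts.counts[keep]
    factors = size_factors(sub, allow_pseudo_reference=True)
    cond = _condition_series(sheet, keep, case)
    disp = estimate_dispersion(sub, factors, cond)
    return wald_dmr_test(sub, factors, disp, cond, case=case, reference="control")


def subgroup_dmr(
    counts: CountMatrix,
    sheet: SampleSheet,
    case: str = "OC",
    control_subset: str = "both",
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Contrast the case group against one control subset or both."""
    mapping = {
        "benign": ("benign",),
        "healthy": ("healthy",),
        "both": ("benign", "healthy"),
    }
    if control_subset not in mapping:
        raise ValueError(f"unknown control subset {control_subset!r}; expected one of {list(mapping)}")
    return dmr_analysis(counts, sheet, case=case, control_groups=mapping[control_subset], exclude=exclude)


@dataclass
class RobustSet:
    """Gene sets from the full and leave-one-out analyses."""

    genes_full: set[str]
    genes_reduced: set[str]
    representatives: pd.DataFrame  # from the full analysis, robust genes only

    @property
    def robust_genes(self) -> set[str]:
        return self.genes_full & self.genes_reduced


def robustness_excluding(
    counts: CountMatrix,
    sheet: SampleSheet,
    exclude: str,
    gene_bodies: Sequence[GInterval],
    alpha: float = 0.1,
    full_table: pd.DataFrame | None = None,
) -> RobustSet:
    """Repeat the DMR analysis without one sample and intersect gene sets.

    Both runs (full cohort and reduced cohort) recompute size factors,
    dispersions and the test from scratch; genes present in both called
    gene sets are the robust set, represented by their lowest-padj DMR from
    the full analysis.
    """
    if exclude not in counts.samples:
        raise ValueError(f"sample {exclude!r} not in count matrix")
    if full_table is None:
        full_table = dmr_analysis(counts, sheet)
    reduced_table = dmr_analysis(counts, sheet, exclude=[exclude])

    full_called, _ = call_dmrs(full_table, alpha)
    reduced_called, _ = call_dmrs(reduced_table, alpha)
    genes_full = map_dmrs_to_genes(full_called, gene_bodies, counts.grid)
    genes_reduced = map_dmrs_to_genes(reduced_called, gene_bodies, counts.grid)
    robust = set(genes_full.index) & set(genes_reduced.index)
    reps = genes_full.loc[sorted(robust)] if robust else genes_full.iloc[:0]
    return RobustSet(
        genes_full=set(genes_full.index),
        genes_reduced=set(genes_reduced.index),
        representatives=reps,
    )


# ---------------------------------------------------------------------------
# Reporting


def attach_coordinates(table: pd.DataFrame, grid: BinGrid) -> pd.DataFrame:
    """Add chrom / start_1based / stop_1based report columns (inclusive)."""
    coords = grid.to_frame().loc[table.index]
    out = table.copy()
    out.insert(0, "chrom", coords["chrom"])
    out.insert(1, "start_1based", coords["start"] + 1)
    out.insert(2, "stop_1based", coords["end"])
    return out


def write_dmr_table(table: pd.DataFrame, grid: BinGrid, path: str | Path) -> None:
    attach_coordinates(table, grid).to_csv(
        path, sep="\t", index_label="bin_id", float_format="%.6g"
    )
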