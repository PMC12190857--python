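"""Exploratory transforms: variance stabilization, SVD batch check,
k-means/PCA sample clustering, and the robust-gene heatmap matrix.

The variance-stabilizing transform used here is the simple monotone
``log2(count / size_factor + 1)`` — sufficient to flatten the count-mean
dependence for decomposition-based batch checks, and named honestly in all
outputs (``vst`` provenance means exactly this transform).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .filters import SampleSheet

__all__ = [
    "vst",
    "svd_batch_check",
    "top_variance_bins",
    "kmeans_cluster",
    "heatmap_matrix",
]


def vst(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), bins x samples."""
    f = factors.loc[counts.columns].to_numpy(dtype=float)
    if (f <= 0).any():
        raise ValueError("size factors must be positive")
    return pd.DataFrame(
        np.log2(counts.to_numpy(dtype=float) / f[None, :] + 1.0),
        index=counts.index,
        columns=counts.columns,
    )


def svd_batch_check(matrix: pd.DataFrame, batches: pd.Series) -> dict:
    """Row-centered SVD of a bins x samples matrix + one-way ANOVA of the
    first two sample score vectors across library batches.

    Returns p_sv1, p_sv2, and the variance fraction explained by the first
    two components.  Degenerate decompositions (zero singular values or
    within-batch constancy) yield NaN p-values.
    """
    b = batches.loc[matrix.columns]
    sizes = b.value_counts()
    if len(sizes) < 2:
        raise ValueError("batch check requires >= 2 batches")
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"each batch needs >= 2 samples; too small: {small}")
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    var_explained = [float(sv**2) / total if total > 0 else float("nan") for sv in s[:2]]

    pvals = []
    for comp in range(2):
        if comp >= len(s) or s[comp] <= 1e-12 * max(s[0], 1.0):
            pvals.append(float("nan"))
            continue
        scores = vt[comp] * s[comp]
        # fix sign: largest-magnitude score positive
        if scores[np.argmax(np.abs(scores))] < 0:
            scores = -scores
        groups = [scores[(b == level).to_numpy()] for level in sizes.index]
        if all(np.allclose(g, g[0]) for g in groups):
            pvals.append(float("nan"))
            continue
        with np.errstate(invalid="ignore"):
            stat, p = stats.f_oneway(*groups)
        pvals.append(float(p) if np.isfinite(p) else float("nan"))
    return {
        "p_sv1": pvals[0],
        "p_sv2": pvals[1],
        "var_explained_sv1": var_explained[0] if len(var_explained) > 0 else float("nan"),
        "var_explained_sv2": var_explained[1] if len(var_explained) > 1 else float("nan"),
    }


def top_variance_bins(counts: pd.DataFrame, k: int = 10_000) -> pd.Index:
    """The k bins with the largest row-wise variance across samples.

    Ties resolve to the lower bin index (stable sort); selection is
    invariant to sample column order.
    """
    if k > counts.shape[0]:
        raise ValueError(f"k = {k} exceeds number of bins ({counts.shape[0]})")
    var = counts.to_numpy(dtype=float).var(axis=1, ddof=1)
    order = np.argsort(-var, kind="stable")[:k]
    return counts.index[np.sort(order)]


def kmeans_cluster(
    matrix: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    restarts: int = 10,
) -> tuple[pd.Series, pd.DataFrame, float]:
    """K-means over the *columns* (samples) of a bins x samples matrix.

    Best of `restarts` k-means++ runs by within-cluster sum of squares;
    also returns 2-component PCA sample coordinates (sign fixed so the
    largest-magnitude loading of each component is positive) for plotting.
    """
    X = matrix.to_numpy(dtype=float).T  # samples x bins
    if k > X.shape[0]:
        raise ValueError(f"k = {k} exceeds number of samples ({X.shape[0]})")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(X)
    n_comp = min(2, X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    coords = pca.fit_transform(X - X.mean(axis=0, keepdims=True))
    for j in range(coords.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] = -coords[:, j]
    if coords.shape[1] < 2:
        coords = np.column_stack([coords, np.zeros(coords.shape[0])])
    assign = pd.Series(labels, index=matrix.columns, name="cluster")
    frame = pd.DataFrame(coords[:, :2], index=matrix.columns, columns=["PC1", "PC2"])
    return assign, frame, float(km.inertia_)


def heatmap_matrix(
    counts: pd.DataFrame,
    representatives: pd.DataFrame,
    sheet: SampleSheet,
    group_order: Sequence[str] = ("OC", "benign", "healthy"),
) -> pd.DataFrame:
    """Row-scaled log2 signal matrix for the robust-gene heatmap.

    `representatives` is the gene-indexed table from the gene-mapping step
    (column ``bin_id`` selects the representative DMR per gene).  Values
    are log2(count + 1), then per-row standardized to mean 0 / SD 1
    (ddof 0).  Columns are ordered by diagnostic group, stably by sample id
    within a group; rows keep the representatives' gene order.  A constant
    row is emitted as zeros with a warning.
    """
    missing = [g for g, row in representatives.iterrows() if int(row["bin_id"]) not in counts.index]
    if missing:
        raise KeyError(f"genes whose representative DMR is not in the filtered counts: {missing}")
    order = []
    for group in group_order:
        members = sorted(set(sheet.ids(group)) & set(counts.columns))
        order.extend(members)
    if not order:
        raise ValueError("no samples from the requested groups in the count matrix")
    bin_ids = [int(row["bin_id"]) for _, row in representatives.iterrows()]
    mat = np.log2(counts.loc[bin_ids, order].to_numpy(dtype=float) + 1.0)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    flat = (sd.ravel() == 0)
    if flat.any():
        genes = [g for g, f in zip(representatives.index, flat) if f]
        warnings.warn(f"constant heatmap rows zeroed for genes: {genes}")
    scaled = np.where(sd > 0, (mat - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(scaled, index=representatives.index, columns=order)
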