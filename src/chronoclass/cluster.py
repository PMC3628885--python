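"""Correlation-metric hierarchical clustering of expression profiles.

Distances are 1 - Pearson r between gene rows (pairwise-complete over
non-missing samples), clustered agglomeratively with average (default) or
complete linkage.  Output includes the scipy linkage matrix, a deterministic
leaf order, and a Newick rendering of the dendrogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .errors import InputError

MIN_SHARED_SAMPLES = 3


def correlation_distance(matrix, method: str = "pearson") -> np.ndarray:
    """Symmetric distance matrix d(i,j) = 1 - r(row_i, row_j) in [0, 2].

    Correlations are computed over the samples where both rows are
    non-missing.  Rows with zero variance are rejected; pairs sharing fewer
    than 3 samples get the maximal distance 2 with a warning.
    """
    X = matrix.values if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("need a 2-D matrix with >= 2 rows")
    if method == "spearman":
        X = _rank_rows(X)
    elif method != "pearson":
        raise InputError(f"unknown correlation method {method!r}")
    mask = np.isfinite(X)
    for i in range(X.shape[0]):
        row = X[i, mask[i]]
        if row.size and np.ptp(row) == 0:
            raise InputError(f"row {i} has zero variance")
    if mask.all():
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(X)
        d = 1.0 - r
    else:
        n = X.shape[0]
        d = np.zeros((n, n))
        thin = 0
        for i in range(n):
            for j in range(i + 1, n):
                shared = mask[i] & mask[j]
                if shared.sum() < MIN_SHARED_SAMPLES:
                    d[i, j] = d[j, i] = 2.0
                    thin += 1
                    continue
                xi, xj = X[i, shared], X[j, shared]
                if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                    d[i, j] = d[j, i] = 2.0
                    thin += 1
                    continue
                r = np.corrcoef(xi, xj)[0, 1]
                d[i, j] = d[j, i] = 1.0 - r
        if thin:
            warnings.warn(
                f"{thin} gene pairs shared < {MIN_SHARED_SAMPLES} samples or were "
                "degenerate; their distance was set to the maximum (2)",
                stacklevel=2,
            )
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _rank_rows(X: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    out = np.full_like(X, np.nan, dtype=float)
    for i in range(X.shape[0]):
        ok = np.isfinite(X[i])
        out[i, ok] = rankdata(X[i, ok])
    return out


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: np.ndarray  # permutation of input row indices
    labels: list

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        buf = StringIO()
        tree.write(buf, format="newick")
        return buf.getvalue().strip()

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster ids (1-based) cutting the tree into n clusters."""
        return hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")


def hierarchical_cluster(
    dist: np.ndarray, linkage: str = "average", labels=None
) -> ClusterResult:
    """Agglomerative clustering of a precomputed distance matrix.

    Ties are resolved deterministically (scipy merges the earliest eligible
    pair, so lower original indices come first).  ``linkage`` is ``average``
    or ``complete``.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise InputError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise InputError("distance matrix must be symmetric")
    if linkage not in ("average", "complete"):
        raise InputError(f"unsupported linkage {linkage!r}")
    if labels is None:
        labels = [str(i) for i in range(dist.shape[0])]
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    order = np.asarray(hierarchy.leaves_list(Z))
    return ClusterResult(linkage=Z, leaf_order=order, labels=list(labels))


def cluster_matrix(
    matrix: pd.DataFrame,
    linkage: str = "average",
    method: str = "pearson",
) -> tuple:
    """Cluster genes (rows) and samples (columns) of an expression matrix.

    Returns ``(gene_result, sample_result)``; sample clustering uses the
    same correlation metric on the transposed matrix.
    """
    genes = hierarchical_cluster(
        correlation_distance(matrix, method), linkage, labels=list(matrix.index)
    )
    cols = hierarchical_cluster(
        correlation_distance(matrix.T, method), linkage, labels=list(matrix.columns)
    )
    return genes, cols


CATEGORY_COLORS = {"fetal": "#2c5aa0", "young": "#c0392b", "adult": "#1e8449"}


def plot_heatmap(matrix: pd.DataFrame, gene_result, sample_result,
                 categories, path) -> None:
    """Clustered heatmap with an age-category colour bar (PNG side output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = matrix.iloc[gene_result.leaf_order, sample_result.leaf_order]
    cats = np.asarray(categories)[sample_result.leaf_order]
    fig, (ax_bar, ax) = plt.subplots(
        2, 1, figsize=(8, 10), height_ratios=[0.3, 9.7], sharex=False
    )
    ax_bar.imshow(
        [[list(CATEGORY_COLORS).index(c) for c in cats]],
        aspect="auto",
        cmap=matplotlib.colors.ListedColormap(list(CATEGORY_COLORS.values())),
    )
    ax_bar.set_axis_off()
    vmax = np.nanpercentile(np.abs(ordered.values), 98)
    ax.imshow(ordered.values, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xlabel("samples (clustered)")
    ax.set_ylabel("genes (clustered)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
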