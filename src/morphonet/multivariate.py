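"""Scaling, PCA, Ward hierarchical clustering and heatmap ordering.

The networks x measures table feeds two complementary multivariate views:
a correlation PCA (measures span many orders of magnitude, so columns are
z-scored by default) and an agglomerative HCA with Ward.D2 linkage on
Euclidean distances of the scaled table, whose dendrogram plays the role of
a hypothetical evolutionary tree. The cophenetic correlation quantifies how
faithfully that ultrametric tree represents the original distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans


def scale_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column z-scores (mean 0, sample standard deviation 1, ddof=1).

    Constant columns carry no information and are dropped with a warning;
    an all-constant table is an error.
    """
    sd = table.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns are constant; nothing to scale")
    if not keep.all():
        dropped = list(table.columns[~keep])
        warnings.warn(f"dropping constant columns: {dropped}", UserWarning, stacklevel=2)
        table = table.loc[:, keep]
        sd = sd[keep]
    return (table - table.mean(axis=0)) / sd


@dataclass
class PCAResult:
    """Scores (rows x components), loadings (columns x components) and
    percent variance explained per component, ordered by variance."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray  # percentages

    def cumulative(self, k: int) -> float:
        return float(self.variance_explained[:k].sum())


def pca(table: pd.DataFrame, scale: bool = True) -> PCAResult:
    """Principal component analysis by SVD of the centered (and, by default,
    scaled) table, matching the R ``prcomp`` convention (ddof=1 scaling)."""
    if table.shape[0] < 3:
        raise ValueError("PCA needs at least 3 rows")
    x = scale_table(table) if scale else table - table.mean(axis=0)
    u, s, vt = np.linalg.svd(x.to_numpy(), full_matrices=False)
    var = s ** 2
    var_pct = 100.0 * var / var.sum()
    ncomp = len(s)
    comps = [f"PC{i + 1}" for i in range(ncomp)]
    scores = pd.DataFrame(u * s, index=x.index, columns=comps)
    loadings = pd.DataFrame(vt.T, index=x.columns, columns=comps)
    return PCAResult(scores=scores, loadings=loadings, variance_explained=var_pct)


@dataclass
class HCAResult:
    """Ward.D2 agglomeration result.

    ``linkage`` is a scipy linkage matrix over ``labels``; ``heights`` its
    merge heights; ``assignments`` the k-cut; ``cophenetic`` the condensed
    ultrametric distance vector and ``cophenetic_correlation`` its Pearson
    correlation with the input Euclidean distances.
    """

    labels: list[str]
    linkage: np.ndarray
    assignments: pd.Series
    cophenetic: np.ndarray
    cophenetic_correlation: float
    k: int

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(squareform(self.cophenetic),
                            index=self.labels, columns=self.labels)

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            children = ",".join(rec(c, node.dist) for c in (node.left, node.right))
            return f"({children}):{length:.10g}"

        return rec(tree, tree.dist) + ";"


def hca(table: pd.DataFrame, k: int = 4, scale: bool = True) -> HCAResult:
    """Agglomerative clustering with the Ward.D2 update on Euclidean distances.

    scipy's ``ward`` linkage on raw observations implements exactly the
    Ward.D2 semantics (squared-Euclidean objective, square-rooted heights).
    Ties are broken deterministically by scipy's lowest-index convention.
    """
    if not 1 <= k <= table.shape[0]:
        raise ValueError(f"cluster count k={k} out of range [1, {table.shape[0]}]")
    x = scale_table(table) if scale else table
    dist = pdist(x.to_numpy(), metric="euclidean")
    z = hierarchy.linkage(dist, method="ward")
    coph_corr, coph = hierarchy.cophenet(z, dist)
    labels_at_k = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return HCAResult(
        labels=list(table.index),
        linkage=z,
        assignments=pd.Series(labels_at_k, index=table.index, name="cluster"),
        cophenetic=coph,
        cophenetic_correlation=float(coph_corr),
        k=k,
    )


def hkmeans(table: pd.DataFrame, k: int = 4, scale: bool = True,
            max_iter: int = 300) -> pd.Series:
    """Hierarchical k-means: k-means seeded from the HCA k-cut centroids.

    Combines the determinism of the tree cut with k-means refinement; with
    well-separated groups the assignment coincides with the tree cut.
    """
    x = scale_table(table) if scale else table
    tree = hca(table, k=k, scale=scale)
    centroids = np.vstack([
        x.to_numpy()[tree.assignments.to_numpy() == c].mean(axis=0)
        for c in range(1, k + 1)
    ])
    km = KMeans(n_clusters=k, init=centroids, n_init=1, max_iter=max_iter)
    labels = km.fit_predict(x.to_numpy()) + 1
    return pd.Series(labels, index=table.index, name="cluster")


def heatmap_order(networks_hca: HCAResult, measures_hca: HCAResult,
                  table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Reorder rows/columns to dendrogram leaf order and attach group labels.

    Returns (ordered scaled table, network cluster labels, measure cluster
    labels), the ingredients of the clustered-heatmap display.
    """
    if set(networks_hca.labels) != set(table.index):
        raise ValueError("network tree labels do not match table rows")
    if set(measures_hca.labels) != set(table.columns):
        raise ValueError("measure tree labels do not match table columns")
    row_order = networks_hca.leaf_order()
    col_order = measures_hca.leaf_order()
    ordered = table.loc[row_order, col_order]
    return (ordered,
            networks_hca.assignments.loc[row_order],
            measures_hca.assignments.loc[col_order])
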