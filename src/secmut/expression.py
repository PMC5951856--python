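"""Expression correlation maps: log-TPM transform, high-variance gene
selection, Pearson correlation, hierarchical clustering.

TPM values are transformed as log2(1 + TPM); the 500 genes of highest
post-transform variance (zero-variance genes dropped first, ties broken by
gene id) feed a sample-by-sample Pearson correlation matrix, which is
clustered hierarchically (complete linkage on Euclidean distances between
correlation rows).  Two robustness gene sets are available: all genes with
variance above a cutoff, and the full transcriptome.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

DEFAULT_TOP_N = 500


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(1 + TPM); validates non-negativity and unique ids."""
    if (matrix < 0).any().any():
        raise ValueError("TPM values must be non-negative")
    if matrix.index.duplicated().any() or matrix.columns.duplicated().any():
        raise ValueError("gene and sample ids must be unique")
    return np.log2(1.0 + matrix)


def select_genes(
    log_matrix: pd.DataFrame,
    top_n: Optional[int] = DEFAULT_TOP_N,
    min_variance: Optional[float] = None,
) -> pd.DataFrame:
    """High-variance gene selection on the transformed matrix.

    ``top_n`` keeps the n most variable genes (after removing zero-variance
    genes; ties at the boundary broken by gene id).  ``min_variance`` instead
    keeps all genes above the cutoff; both None keeps the full transcriptome.
    """
    var = log_matrix.var(axis=1, ddof=1)
    if min_variance is not None:
        return log_matrix.loc[var > min_variance]
    if top_n is None:
        return log_matrix
    nonzero = var[var > 0]
    if top_n > len(nonzero):
        raise ValueError(
            f"top_n={top_n} exceeds the {len(nonzero)} genes with non-zero variance"
        )
    ranked = nonzero.sort_index().sort_values(ascending=False, kind="stable")
    return log_matrix.loc[ranked.index[:top_n].sort_values()]


class CorrelationCluster(BaseEstimator):
    """Sample-correlation map with hierarchical clustering (sklearn style).

    Parameters
    ----------
    top_n : int or None
        Number of highest-variance genes to retain (default 500).
    min_variance : float or None
        Alternative selection: keep genes with variance above this cutoff.
    method, metric : str
        Linkage method and inter-row distance for clustering (defaults:
        complete linkage, Euclidean).

    Attributes
    ----------
    correlation_ : pd.DataFrame
        Sample-by-sample Pearson correlations.
    linkage_ : np.ndarray
        scipy linkage matrix.
    order_ : list[str]
        Dendrogram leaf order.
    """

    def __init__(
        self,
        top_n: Optional[int] = DEFAULT_TOP_N,
        min_variance: Optional[float] = None,
        method: str = "complete",
        metric: str = "euclidean",
    ):
        self.top_n = top_n
        self.min_variance = min_variance
        self.method = method
        self.metric = metric

    def fit(self, X: pd.DataFrame, y=None) -> "CorrelationCluster":
        if X.shape[1] < 2:
            raise ValueError("at least two samples are required")
        logm = log_transform(X)
        selected = select_genes(logm, self.top_n, self.min_variance)
        corr = selected.corr(method="pearson")  # samples x samples
        dist = pdist(corr.to_numpy(), metric=self.metric)
        self.linkage_ = hierarchy.linkage(dist, method=self.method)
        leaves = hierarchy.leaves_list(self.linkage_)
        self.correlation_ = corr
        self.order_ = [corr.columns[i] for i in leaves]
        self.genes_used_ = list(selected.index)
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).correlation_

    def to_newick(self) -> str:
        """Dendrogram in Newick format."""
        tree = hierarchy.to_tree(self.linkage_)
        labels = list(self.correlation_.columns)

        def _rec(node) -> str:
            if node.is_leaf():
                return labels[node.id]
            return f"({_rec(node.left)},{_rec(node.right)}):{node.dist:.6g}"

        return _rec(tree) + ";"


def correlation_map(
    matrix: pd.DataFrame,
    top_n: Optional[int] = DEFAULT_TOP_N,
    min_variance: Optional[float] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """(correlation matrix, dendrogram order); see :class:`CorrelationCluster`."""
    cc = CorrelationCluster(top_n=top_n, min_variance=min_variance).fit(matrix)
    return cc.correlation_, cc.order_
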