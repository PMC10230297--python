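"""Similarity and hierarchical clustering of rescaled mobility series.

The cross-validation design: date-aligned percent-of-baseline series from
different sources (the in-app panel index next to external report metrics)
are compared by Euclidean distance and agglomerated with unweighted average
linkage (UPGMA-style inter-cluster mean distance). Outlying series are kept
on purpose — they carry the information about how differently a metric
reacts to external shocks — which is why average linkage is used rather
than single or Ward linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from mobigrid.errors import AlignmentError, ParameterError


@dataclass
class Dendrogram:
    """Merge sequence from agglomerative clustering.

    ``linkage`` is the (n-1, 4) scipy linkage matrix — rows are
    (left, right, height, size) with heights non-decreasing for average
    linkage on a metric; ``labels`` names the leaves in input order.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def distance_matrix(series: pd.DataFrame, window_start, window_end,
                    value_col: str = "pct") -> tuple[list[str], np.ndarray]:
    """Pairwise Euclidean distances between date-aligned series vectors.

    Every series must be complete on the (inclusive) window — interpolate
    first if needed; an incomplete series raises an alignment error naming
    it. Returns (labels, symmetric distance matrix).
    """
    start = pd.Timestamp(window_start).date()
    end = pd.Timestamp(window_end).date()
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df = df[(df["date"] >= start) & (df["date"] <= end)]
    wide = df.pivot_table(index="date", columns="series_id", values=value_col,
                          aggfunc="first")
    expected = pd.date_range(start, end, freq="D")
    wide = wide.reindex([t.date() for t in expected])
    bad = sorted(wide.columns[wide.isna().any(axis=0)])
    if bad:
        raise AlignmentError(f"series incomplete on window {start}..{end}: {bad}")
    labels = sorted(wide.columns)
    mat = wide[labels].to_numpy().T
    return list(labels), squareform(pdist(mat, metric="euclidean"))


class AverageLinkageClustering(BaseEstimator):
    """Agglomerative clustering with unweighted average linkage on a
    precomputed distance matrix.

    Ties in the minimum inter-cluster distance are resolved by feeding the
    leaves in lexicographic label order, making the merge sequence
    deterministic and order-invariant up to that rule.

    Parameters
    ----------
    n_clusters : number of flat clusters returned in ``labels_``

    Attributes (after ``fit``)
    ----------
    dendrogram_ : the full merge sequence
    labels_ : flat cluster assignment at ``n_clusters``
    """

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def fit(self, X: np.ndarray, y=None, leaf_labels: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ParameterError("X must be a square distance matrix")
        n = X.shape[0]
        if n < 2:
            raise ParameterError("need at least 2 series to cluster")
        if not np.allclose(X, X.T) or not np.allclose(np.diag(X), 0):
            raise ParameterError("X must be symmetric with a zero diagonal")
        labels = list(leaf_labels) if leaf_labels is not None else [str(i) for i in range(n)]
        order = np.argsort(np.array(labels, dtype=object))
        X = X[np.ix_(order, order)]
        labels = [labels[i] for i in order]
        Z = sch.linkage(squareform(X, checks=False), method="average")
        self.dendrogram_ = Dendrogram(linkage=Z, labels=labels)
        self.labels_ = cut_tree(self.dendrogram_, self.n_clusters)
        return self

    def fit_predict(self, X, y=None, leaf_labels=None) -> dict[str, int]:
        return self.fit(X, leaf_labels=leaf_labels).labels_


def average_linkage(dist: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """Functional wrapper: distance matrix -> average-linkage dendrogram."""
    est = AverageLinkageClustering(n_clusters=1).fit(dist, leaf_labels=labels)
    return est.dendrogram_


def cut_tree(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Flat clustering with k clusters, removing the k-1 highest merges."""
    n = len(dendrogram.labels)
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    assignment = sch.cut_tree(dendrogram.linkage, n_clusters=k).ravel()
    return dict(zip(dendrogram.labels, (int(c) for c in assignment)))


def to_newick(dendrogram: Dendrogram) -> str:
    """Export the dendrogram as a Newick string with branch lengths equal
    to the drop in merge height from parent to child."""
    tree = sch.to_tree(dendrogram.linkage)
    labels = dendrogram.labels

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    left = rec(tree.get_left(), tree.dist)
    right = rec(tree.get_right(), tree.dist)
    return f"({left},{right});"
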