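"""Cluster similarity via subsampled mutual nearest neighbors.

To compare query epithelial clusters with reference secretory-cell subtypes
without cluster-size bias, a fixed number of cells (default 20) is sampled
from each query cluster.  Mutual nearest neighbors (MNN) between the
subsampled query and the reference are found on a shared gene space (cosine
distance on log-normalized expression by default), and each
(cluster, subtype) combination is scored by its share of all MNN pairs —
scores over all combinations sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "SubtypeReference",
    "SimilarityMatrix",
    "subsample_clusters",
    "find_mnn_pairs",
    "similarity_scores",
    "MNNSimilarityScorer",
]


@dataclass
class SubtypeReference:
    """Reference cells with known subtype labels on a shared gene space."""

    expression: np.ndarray  # cells x genes, normalized
    subtype_of_cell: np.ndarray

    def __post_init__(self) -> None:
        self.expression = _dense(self.expression)
        self.subtype_of_cell = np.asarray(self.subtype_of_cell, dtype=object)
        if self.expression.shape[0] != len(self.subtype_of_cell):
            raise ValueError("one subtype label per reference cell required")
        if len(pd.unique(self.subtype_of_cell)) < 2:
            raise ValueError("reference must hold at least 2 subtypes")


@dataclass
class SimilarityMatrix:
    scores: pd.DataFrame  # clusters x subtypes
    n_pairs: pd.DataFrame
    total_pairs: int


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)


def subsample_clusters(
    X: np.ndarray,
    cluster_labels: np.ndarray,
    k: int = 20,
    min_cluster_size: int = 21,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample ``k`` cells without replacement from each sufficiently large cluster.

    Returns (subsampled cells x genes, their cluster labels, original row
    indices).  Clusters below ``min_cluster_size`` are excluded with a
    warning; clusters with size in [k, min_cluster_size) cannot occur at the
    defaults (min_cluster_size > k); if k exceeds an included cluster's size
    the whole cluster is taken with a warning.
    """
    X = _dense(X)
    cluster_labels = np.asarray(cluster_labels)
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    for cluster in pd.unique(cluster_labels):
        idx = np.flatnonzero(cluster_labels == cluster)
        if len(idx) < min_cluster_size:
            warnings.warn(f"cluster {cluster} has {len(idx)} cells (< {min_cluster_size}); excluded")
            continue
        if k >= len(idx):
            warnings.warn(f"cluster {cluster} has only {len(idx)} cells; taking all")
            take = idx
        else:
            take = np.sort(rng.choice(idx, size=k, replace=False))
        rows.append(take)
    if not rows:
        raise ValueError("no cluster is large enough to subsample")
    sel = np.concatenate(rows)
    return X[sel], cluster_labels[sel], sel


def find_mnn_pairs(
    query: np.ndarray,
    reference: np.ndarray,
    k_nn: int = 20,
    metric: str = "cosine",
) -> list[tuple[int, int]]:
    """Mutual nearest neighbor pairs between query and reference cells.

    (a, b) is a pair iff b is among the k nearest reference cells of a AND
    a is among the k nearest query cells of b.  Brute-force search keeps
    tie handling deterministic (stable by cell index).
    """
    query, reference = _dense(query), _dense(reference)
    if query.shape[1] != reference.shape[1]:
        raise ValueError("query and reference must share the gene space")
    if query.shape[1] == 0:
        raise ValueError("empty shared gene space")
    k_q = min(k_nn, reference.shape[0])
    k_r = min(k_nn, query.shape[0])
    nn_ref = NearestNeighbors(n_neighbors=k_q, metric=metric, algorithm="brute").fit(reference)
    fwd = nn_ref.kneighbors(query, return_distance=False)
    nn_query = NearestNeighbors(n_neighbors=k_r, metric=metric, algorithm="brute").fit(query)
    bwd = nn_query.kneighbors(reference, return_distance=False)
    bwd_sets = [set(row) for row in bwd]
    pairs = []
    for a in range(query.shape[0]):
        for b in sorted(fwd[a]):
            if a in bwd_sets[b]:
                pairs.append((a, int(b)))
    return pairs


def similarity_scores(
    pairs: list[tuple[int, int]],
    cluster_of_query_cell: np.ndarray,
    subtype_of_ref_cell: np.ndarray,
) -> SimilarityMatrix:
    """Pair-share similarity: score(c, s) = #pairs(c, s) / #pairs total."""
    cluster_of_query_cell = np.asarray(cluster_of_query_cell)
    subtype_of_ref_cell = np.asarray(subtype_of_ref_cell)
    clusters = list(pd.unique(cluster_of_query_cell))
    subtypes = list(pd.unique(subtype_of_ref_cell))
    counts = pd.DataFrame(0, index=clusters, columns=subtypes, dtype=int)
    for a, b in pairs:
        counts.loc[cluster_of_query_cell[a], subtype_of_ref_cell[b]] += 1
    total = int(counts.to_numpy().sum())
    if total == 0:
        warnings.warn("no MNN pairs found; similarity scores are all zero")
        scores = counts.astype(float)
    else:
        scores = counts / total
    return SimilarityMatrix(scores=scores, n_pairs=counts, total_pairs=total)


class MNNSimilarityScorer(BaseEstimator):
    """Subsample + MNN + pair-share similarity, sklearn-style.

    ``fit(reference_expression, subtype_labels)`` stores the reference;
    ``transform(query_expression, cluster_labels)`` returns the
    :class:`SimilarityMatrix` for the query clusters.
    """

    def __init__(
        self,
        k_subsample: int = 20,
        k_nn: int = 20,
        metric: str = "cosine",
        min_cluster_size: int = 21,
        seed: int = 0,
    ):
        self.k_subsample = k_subsample
        self.k_nn = k_nn
        self.metric = metric
        self.min_cluster_size = min_cluster_size
        self.seed = seed

    def fit(self, X, y):
        self.reference_ = SubtypeReference(X, np.asarray(y))
        counts = pd.Series(self.reference_.subtype_of_cell).value_counts()
        if (counts < self.k_nn).any():
            warnings.warn("some reference subtypes have fewer cells than k_nn")
        return self

    def transform(self, X, cluster_labels) -> SimilarityMatrix:
        sub_X, sub_labels, _ = subsample_clusters(
            X, cluster_labels, k=self.k_subsample, min_cluster_size=self.min_cluster_size, seed=self.seed
        )
        pairs = find_mnn_pairs(sub_X, self.reference_.expression, k_nn=self.k_nn, metric=self.metric)
        return similarity_scores(pairs, sub_labels, self.reference_.subtype_of_cell)


def similarity_table(sim: SimilarityMatrix) -> pd.DataFrame:
    rows = []
    for cluster in sim.scores.index:
        for subtype in sim.scores.columns:
            rows.append(
                {
                    "cluster": cluster,
                    "subtype": subtype,
                    "n_pairs": int(sim.n_pairs.loc[cluster, subtype]),
                    "score": float(sim.scores.loc[cluster, subtype]),
                }
            )
    return pd.DataFrame(rows)
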