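"""Marker-based cell typing for fallopian-tube mucosa.

Major types are assigned per cluster by panel-mean marker scores
(epithelial EPCAM/KRT18, fibroblast DCN, T cell CD3D/E/G, macrophage CD68,
endothelial PECAM1).  Epithelial cells are further split by PAX8/TP73
detection into secretory (PAX8+ only), ciliated (TP73+ only) and transition
(both) subtypes; "detected" means raw count >= 1.

Clustering itself is pluggable plumbing: any per-cell labels are accepted,
and :func:`cluster_cells` provides a seeded k-means-on-PCs default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ExpressionMatrix

__all__ = [
    "MarkerPanel",
    "DEFAULT_PANELS",
    "EPITHELIAL_SUBTYPES",
    "score_cell_types",
    "annotate_clusters",
    "classify_epithelial",
    "cluster_cells",
    "annotation_table",
    "major_type_summary",
]


@dataclass(frozen=True)
class MarkerPanel:
    type_name: str
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker panel must be non-empty")


DEFAULT_PANELS: tuple[MarkerPanel, ...] = (
    MarkerPanel("epithelial", ("EPCAM", "KRT18")),
    MarkerPanel("fibroblast", ("DCN",)),
    MarkerPanel("T", ("CD3D", "CD3E", "CD3G")),
    MarkerPanel("macrophage", ("CD68",)),
    MarkerPanel("endothelial", ("PECAM1",)),
)

EPITHELIAL_SUBTYPES = ("secretory", "ciliated", "transition", "unassigned")


def score_cell_types(
    norm_matrix: sp.spmatrix,
    gene_symbols: list[str],
    panels: tuple[MarkerPanel, ...] = DEFAULT_PANELS,
) -> pd.DataFrame:
    """Per-cell marker score for each type: mean normalized expression
    of the panel's markers present in the matrix.

    Markers absent from the matrix are dropped with a warning; a panel with
    no present markers is a configuration error.
    """
    sym_to_row = {s: i for i, s in enumerate(gene_symbols)}
    norm = sp.csr_matrix(norm_matrix)
    scores = {}
    for panel in panels:
        rows = [sym_to_row[m] for m in panel.markers if m in sym_to_row]
        missing = [m for m in panel.markers if m not in sym_to_row]
        if missing:
            warnings.warn(f"panel {panel.type_name}: marker(s) not in matrix: {', '.join(missing)}")
        if not rows:
            raise ValueError(f"panel {panel.type_name} has no marker present in the matrix")
        scores[panel.type_name] = np.asarray(norm[rows].mean(axis=0)).ravel()
    return pd.DataFrame(scores)


def annotate_clusters(scores: pd.DataFrame, cluster_labels: np.ndarray) -> dict:
    """Map each cluster to the major type with maximal mean marker score.

    An exact tie between the top two mean scores yields ``unassigned``
    (determinism over arbitrary picks).  Order of cells and the naming of
    clusters do not affect the result.
    """
    cluster_labels = np.asarray(cluster_labels)
    if len(cluster_labels) != len(scores):
        raise ValueError("cluster labels must match score rows")
    mapping = {}
    for cluster in pd.unique(cluster_labels):
        members = scores[cluster_labels == cluster]
        if members.empty:
            raise ValueError(f"empty cluster: {cluster}")
        means = members.mean(axis=0)
        order = means.sort_values(ascending=False)
        if len(order) > 1 and order.iloc[0] == order.iloc[1]:
            mapping[cluster] = "unassigned"
        else:
            mapping[cluster] = order.index[0]
    return mapping


def classify_epithelial(
    matrix: ExpressionMatrix,
    epithelial_mask: np.ndarray,
    secretory_marker: str = "PAX8",
    ciliated_marker: str = "TP73",
) -> np.ndarray:
    """Epithelial subtype per cell from raw-count marker detection.

    PAX8 detected & TP73 not -> secretory; TP73 only -> ciliated;
    both -> transition; neither -> unassigned.  Non-epithelial cells get
    ``not_applicable``.
    """
    idx = matrix.symbol_index()
    for m in (secretory_marker, ciliated_marker):
        if m not in idx:
            raise ValueError(f"required epithelial marker absent from matrix: {m}")
    pax8 = np.asarray(matrix.counts[idx[secretory_marker]].todense()).ravel() >= 1
    tp73 = np.asarray(matrix.counts[idx[ciliated_marker]].todense()).ravel() >= 1
    out = np.full(matrix.n_cells, "not_applicable", dtype=object)
    epi = np.asarray(epithelial_mask, dtype=bool)
    out[epi & pax8 & ~tp73] = "secretory"
    out[epi & tp73 & ~pax8] = "ciliated"
    out[epi & pax8 & tp73] = "transition"
    out[epi & ~pax8 & ~tp73] = "unassigned"
    return out


def cluster_cells(
    norm_matrix: sp.spmatrix,
    n_clusters: int = 10,
    n_components: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Default clustering plumbing: k-means on top principal components.

    Any other labeling can be substituted; the annotation stage only needs
    per-cell labels.

    Genes are centered and scaled to unit variance before the decomposition;
    without centering the leading component tracks sequencing depth (through
    the dropout pattern) and shallow cells of every type collapse into one
    cluster.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    X = np.asarray(sp.csr_matrix(norm_matrix).T.todense())  # cells x genes
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    n_components = min(n_components, min(X.shape) - 1)
    pcs = PCA(n_components=n_components, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    return km.fit_predict(pcs)


def annotation_table(
    matrix: ExpressionMatrix,
    cluster_labels: np.ndarray,
    cluster_to_type: dict,
    epithelial_subtype: np.ndarray,
) -> pd.DataFrame:
    """Tidy per-cell annotation (barcode, sample, group, cluster, types)."""
    return pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "sample": matrix.sample_of_cell,
            "group": matrix.group_of_cell,
            "cluster": np.asarray(cluster_labels),
            "major_type": [cluster_to_type[c] for c in cluster_labels],
            "epithelial_subtype": epithelial_subtype,
        }
    )


def major_type_summary(annotations: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary: cell count and percentage per major type.

    Percentages are of all annotated cells, rounded display left to callers;
    e.g. a cohort of 19,008 cells with 3,243 T cells has a T fraction of
    100*3243/19008 = 17.06%.
    """
    counts = annotations["major_type"].value_counts()
    total = int(len(annotations))
    return pd.DataFrame(
        {
            "major_type": counts.index,
            "n_cells": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / total,
        }
    )
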