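"""Quality control and normalization.

Cells with a high mitochondrial read fraction (dying or lysed cells leak
cytoplasmic mRNA while retaining mitochondrial transcripts) are removed at a
configurable threshold, default 15%, with the boundary itself removed.
Expression is then depth-normalized to a fixed scale factor and
log-transformed: ``ln(1 + count / total * scale_factor)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import ExpressionMatrix

__all__ = ["QCConfig", "mito_fraction", "filter_high_mito", "lognormalize", "qc_summary"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCConfig:
    """QC parameters.

    mito_prefix: gene-symbol prefix marking mitochondrial genes.
    mito_threshold: cells with mito fraction >= this are removed.
    scale_factor: per-cell depth target of the normalization.
    """

    mito_prefix: str = "MT-"
    mito_threshold: float = 0.15
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        if not (0.0 < self.mito_threshold <= 1.0):
            raise ValueError("mito_threshold must be in (0, 1]")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


def mito_fraction(matrix: ExpressionMatrix, config: QCConfig = QCConfig()) -> np.ndarray:
    """Per-cell fraction of counts on mitochondrial genes.

    Cells with zero total counts get fraction 0 (with a warning); they carry
    no evidence either way and are left to downstream filters.
    """
    if matrix.n_cells == 0 or matrix.n_genes == 0:
        raise ValueError("matrix is empty")
    mito_rows = np.array(
        [sym.startswith(config.mito_prefix) for sym in matrix.gene_symbols], dtype=bool
    )
    total = np.asarray(matrix.counts.sum(axis=0)).ravel().astype(float)
    mito = np.asarray(matrix.counts[mito_rows].sum(axis=0)).ravel().astype(float)
    frac = np.zeros(matrix.n_cells)
    nonzero = total > 0
    if not nonzero.all():
        warnings.warn(f"{int((~nonzero).sum())} cell(s) with zero total counts; mito fraction set to 0")
    frac[nonzero] = mito[nonzero] / total[nonzero]
    return frac


def filter_high_mito(
    matrix: ExpressionMatrix, config: QCConfig = QCConfig()
) -> ExpressionMatrix:
    """Remove cells whose mitochondrial fraction is >= the threshold.

    The boundary is removed: a cell at exactly the threshold is discarded.
    Removal counts are logged per sample.
    """
    frac = mito_fraction(matrix, config)
    keep = frac < config.mito_threshold
    if not keep.any():
        raise ValueError(
            "QC removed every cell; review mito_threshold "
            f"(= {config.mito_threshold}) against the data"
        )
    for sample in np.unique(matrix.sample_of_cell):
        in_sample = matrix.sample_of_cell == sample
        removed = int((~keep & in_sample).sum())
        log.info("QC sample %s: removed %d of %d cells", sample, removed, int(in_sample.sum()))
    return matrix.subset_cells(keep)


def qc_summary(before: ExpressionMatrix, after: ExpressionMatrix):
    """Per-sample cell counts before/after QC as a tidy table."""
    import pandas as pd

    rows = []
    for sample in np.unique(before.sample_of_cell):
        n_before = int((before.sample_of_cell == sample).sum())
        n_after = int((after.sample_of_cell == sample).sum())
        rows.append({"sample": sample, "cells_before": n_before, "cells_after": n_after})
    return pd.DataFrame(rows)


def lognormalize(
    matrix: ExpressionMatrix, config: QCConfig = QCConfig()
) -> sp.csr_matrix:
    """Depth-normalized log expression: ``ln(1 + count/total * scale_factor)``.

    Returns a sparse genes x cells matrix of floats.  All-zero cells map to
    all-zero columns (warning).  Within a cell the transform is monotone in
    counts and invariant to multiplying every count by a constant.
    """
    total = np.asarray(matrix.counts.sum(axis=0)).ravel().astype(float)
    zero = total == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cell(s) map to all-zero columns")
    scale = np.zeros_like(total)
    scale[~zero] = config.scale_factor / total[~zero]
    norm = sp.csr_matrix(matrix.counts, dtype=float)
    # scale each column then log1p on the nonzeros
    norm = norm.multiply(scale[None, :]).tocsr()
    norm.data = np.log1p(norm.data)
    return sp.csr_matrix(norm)
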