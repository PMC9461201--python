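import numpy as np
import pytest
import scipy.sparse as sp

from fimbria.io import ExpressionMatrix
from fimbria.qc import filter_high_mito, lognormalize
from fimbria.synthetic import CohortConfig, generate_cohort


def small_cohort_config(**overrides) -> CohortConfig:
    """Scaled-down cohort for per-test generation (fast, same structure)."""
    defaults = dict(cells_per_sample=150, n_genes=600, library_size=600)
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(), seed=11)


@pytest.fixture(scope="session")
def qc_cohort(default_cohort):
    """Default cohort after QC, with matching truth rows and log-normalized
    expression."""
    matrix, contigs, truth = default_cohort
    kept = filter_high_mito(matrix)
    keep_mask = np.isin(matrix.barcodes, kept.barcodes)
    return kept, contigs, truth[keep_mask].reset_index(drop=True), lognormalize(kept)


def toy_matrix(counts, symbols=None, groups=None, samples=None) -> ExpressionMatrix:
    """Small dense-count ExpressionMatrix helper for unit tests."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    symbols = symbols or [f"G{i}" for i in range(n_genes)]
    return ExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=[f"ID{i}" for i in range(n_genes)],
        gene_symbols=list(symbols),
        barcodes=[f"cell{j}" for j in range(n_cells)],
        sample_of_cell=np.array(samples or ["s1"] * n_cells, dtype=object),
        group_of_cell=np.array(groups or ["control"] * n_cells, dtype=object),
    )
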