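"""Observed/expected (ROE) enrichment of marker-expressing cells.

For a marker gene and a partition of cells into groups (the two cohorts or
the individual samples), count the cells detecting the marker (raw count
>= 1) per group, form the expected counts under independence
``N_e(g) = (sum_g N_o) * n_cells(g) / (sum_g n_cells)``, and report

    ROE_g = N_o(g) / N_e(g)

ROE > 1 means the group holds more marker-expressing cells than random
allocation would give.  Deviation from independence is tested by a Pearson
chi-squared on the 2 x G expressing/non-expressing table (Yates continuity
correction by default for 2 x 2), with BH adjustment across a marker panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import ExpressionMatrix

__all__ = [
    "MarkerContingency",
    "ROEResult",
    "build_marker_contingency",
    "roe",
    "chisq_independence",
    "roe_panel",
    "EMT_TF_PANEL",
    "EXHAUSTION_PANEL",
]

log = logging.getLogger(__name__)

EMT_TF_PANEL = ("SNAI1", "SNAI2", "ZEB1", "ZEB2", "TWIST1", "TWIST2")
EXHAUSTION_PANEL = ("PDCD1", "HAVCR2", "LAG3", "CTLA4", "TOX", "ENTPD1")


class DegenerateTableError(ValueError):
    """A contingency table with a zero marginal cannot be tested."""


@dataclass
class MarkerContingency:
    marker: str
    groups: tuple[str, ...]
    n_expressing: np.ndarray  # N_o per group
    n_cells: np.ndarray
    n_expected: np.ndarray  # N_e per group

    @property
    def table(self) -> np.ndarray:
        """2 x G counts: expressing / not-expressing by group."""
        return np.vstack([self.n_expressing, self.n_cells - self.n_expressing])


@dataclass
class ROEResult:
    marker: str
    groups: tuple[str, ...]
    roe: np.ndarray
    n_expressing: np.ndarray
    n_expected: np.ndarray
    chi2: float
    p: float
    q: float = np.nan


def build_marker_contingency(
    matrix: ExpressionMatrix,
    marker: str,
    group_of_cell: np.ndarray | None = None,
) -> MarkerContingency:
    """Observed and expected expressing-cell counts per group for one marker.

    ``group_of_cell`` defaults to the matrix's cohort labels; pass the
    per-cell sample labels for a per-sample (2 x 6) table.
    """
    groups_vec = np.asarray(
        matrix.group_of_cell if group_of_cell is None else group_of_cell, dtype=object
    )
    row = matrix.gene_row(marker)
    expressed = np.asarray(matrix.counts[row].todense()).ravel() >= 1
    labels = tuple(pd.unique(groups_vec))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    n_expr = np.array([int(expressed[groups_vec == g].sum()) for g in labels], dtype=float)
    n_cells = np.array([int((groups_vec == g).sum()) for g in labels], dtype=float)
    if (n_cells == 0).any():
        raise ValueError("every group must be nonempty")
    total_expr = n_expr.sum()
    if total_expr == 0:
        raise DegenerateTableError(f"marker {marker} is expressed in zero cells")
    n_exp = total_expr * n_cells / n_cells.sum()
    return MarkerContingency(marker, labels, n_expr, n_cells, n_exp)


def roe(contingency: MarkerContingency) -> np.ndarray:
    """Per-group ROE = N_o / N_e."""
    if (contingency.n_expected <= 0).any():
        raise DegenerateTableError("expected count of zero")
    return contingency.n_expressing / contingency.n_expected


def chisq_independence(table: np.ndarray, yates: bool = True) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a 2 x G count table.

    df = G - 1.  For 2 x 2 tables the Yates continuity correction is applied
    when ``yates`` is true (larger tables are never corrected).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x G table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("table has a zero marginal")
    correction = bool(yates) and table.shape == (2, 2)
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def roe_panel(
    matrix: ExpressionMatrix,
    markers: tuple[str, ...],
    group_of_cell: np.ndarray | None = None,
    yates: bool = True,
) -> list[ROEResult]:
    """ROE + chi-squared for a marker panel, BH-adjusted across markers.

    Markers absent from the matrix or expressed in zero cells are reported
    with ROE/p = NaN and excluded from the BH adjustment.
    """
    results: list[ROEResult] = []
    testable: list[int] = []
    for marker in markers:
        try:
            cont = build_marker_contingency(matrix, marker, group_of_cell)
            stat, p = chisq_independence(cont.table, yates=yates)
            results.append(
                ROEResult(marker, cont.groups, roe(cont), cont.n_expressing, cont.n_expected, stat, p)
            )
            testable.append(len(results) - 1)
        except (KeyError, DegenerateTableError) as exc:
            log.warning("marker %s not testable: %s", marker, exc)
            labels = tuple(
                pd.unique(
                    np.asarray(
                        matrix.group_of_cell if group_of_cell is None else group_of_cell,
                        dtype=object,
                    )
                )
            )
            nan = np.full(len(labels), np.nan)
            results.append(ROEResult(marker, labels, nan, nan, nan, np.nan, np.nan))
    if not testable:
        return results
    q = bh_adjust(np.array([results[i].p for i in testable]))
    for i, qi in zip(testable, q):
        results[i].q = float(qi)
    return results


def roe_table(results: list[ROEResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for g, label in enumerate(r.groups):
            rows.append(
                {
                    "marker": r.marker,
                    "group": label,
                    "N_o": r.n_expressing[g] if np.ndim(r.n_expressing) else np.nan,
                    "N_e": r.n_expected[g] if np.ndim(r.n_expected) else np.nan,
                    "ROE": r.roe[g] if np.ndim(r.roe) else np.nan,
                    "chi2": r.chi2,
                    "p": r.p,
                    "q": r.q,
                }
            )
    return pd.DataFrame(rows)
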