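"""Paired-TCR clonotype calling and clonality/exhaustion statistics.

Cells with exactly one productive full-length TRA and TRB chain (highest-UMI
chain per locus when multiple survive filtering) define clonotypes keyed on
the amino-acid CDR3 pair; a cell is *clonal* when its clonotype holds more
than one cell, pooling all samples.  Clonal expansion between cohorts is a
2 x 2 chi-squared (Yates-corrected); exhaustion markers (PD-1/PDCD1, TIM3,
LAG3, CTLA4, TOX, CD39/ENTPD1) are compared between clonal and non-clonal
cells with two-sided Wilcoxon rank-sum tests and between cohorts with ROE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .io import ExpressionMatrix, TcrChainRecord
from .roe import EXHAUSTION_PANEL, chisq_independence, roe_panel

__all__ = [
    "select_paired_cells",
    "assign_clonotypes",
    "clonality_contingency",
    "clonal_percentages",
    "wilcoxon_marker",
    "exhaustion_analysis",
    "cd8_mask",
]

log = logging.getLogger(__name__)

CLONOTYPE_KEYS = ("cdr3_aa", "cdr3_nt", "v_cdr3_aa")


def _chain_key(record: TcrChainRecord, key: str) -> tuple:
    if key == "cdr3_aa":
        return (record.cdr3_aa,)
    if key == "cdr3_nt":
        return (record.cdr3_nt,)
    if key == "v_cdr3_aa":
        return (record.v_gene, record.cdr3_aa)
    raise ValueError(f"unknown clonotype key: {key}")


def select_paired_cells(chains: Sequence[TcrChainRecord]) -> pd.DataFrame:
    """One row per cell carrying both a TRA and a TRB chain.

    Chains must be called cells, productive and full length; TRA/TRB only.
    When a cell retains several chains of one locus, the highest-UMI chain
    is kept (ties broken by lexicographically smallest nucleotide CDR3).
    Exclusion tallies are logged.
    """
    usable = [
        c for c in chains
        if c.is_cell and c.productive and c.full_length and c.chain in ("TRA", "TRB")
    ]
    log.info("TCR pairing: %d of %d contigs usable", len(usable), len(chains))
    by_cell: dict[str, dict[str, TcrChainRecord]] = {}
    for c in usable:
        slot = by_cell.setdefault(c.barcode, {})
        best = slot.get(c.chain)
        if best is None or (-c.umis, c.cdr3_nt) < (-best.umis, best.cdr3_nt):
            slot[c.chain] = c
    rows = []
    n_unpaired = 0
    for barcode in sorted(by_cell):
        slot = by_cell[barcode]
        if "TRA" not in slot or "TRB" not in slot:
            n_unpaired += 1
            continue
        tra, trb = slot["TRA"], slot["TRB"]
        rows.append(
            {
                "barcode": barcode,
                "tra_v": tra.v_gene, "tra_j": tra.j_gene,
                "tra_cdr3_aa": tra.cdr3_aa, "tra_cdr3_nt": tra.cdr3_nt, "tra_umis": tra.umis,
                "trb_v": trb.v_gene, "trb_j": trb.j_gene,
                "trb_cdr3_aa": trb.cdr3_aa, "trb_cdr3_nt": trb.cdr3_nt, "trb_umis": trb.umis,
            }
        )
    log.info("TCR pairing: %d cells paired, %d single-locus cells excluded", len(rows), n_unpaired)
    columns = [
        "barcode",
        "tra_v", "tra_j", "tra_cdr3_aa", "tra_cdr3_nt", "tra_umis",
        "trb_v", "trb_j", "trb_cdr3_aa", "trb_cdr3_nt", "trb_umis",
    ]
    return pd.DataFrame(rows, columns=columns)


def assign_clonotypes(paired: pd.DataFrame, key: str = "cdr3_aa") -> pd.DataFrame:
    """Clonotype ids, clone sizes and clonal flags for paired cells.

    Identity defaults to the (TRA CDR3aa, TRB CDR3aa) pair; ``cdr3_nt`` and
    ``v_cdr3_aa`` keys are available.  Clone size pools all samples; clonal
    means size >= 2.  The result is independent of input row order.
    """
    if key == "cdr3_aa":
        ident = list(zip(paired["tra_cdr3_aa"], paired["trb_cdr3_aa"]))
    elif key == "cdr3_nt":
        ident = list(zip(paired["tra_cdr3_nt"], paired["trb_cdr3_nt"]))
    elif key == "v_cdr3_aa":
        ident = list(
            zip(paired["tra_v"], paired["tra_cdr3_aa"], paired["trb_v"], paired["trb_cdr3_aa"])
        )
    else:
        raise ValueError(f"unknown clonotype key: {key}")
    out = paired.copy()
    out["_ident"] = ident
    # deterministic ids: clonotypes numbered by sorted identity
    uniq = sorted(set(ident))
    id_of = {u: f"clonotype_{i + 1}" for i, u in enumerate(uniq)}
    sizes = pd.Series(ident).value_counts()
    out["clonotype_id"] = [id_of[u] for u in ident]
    out["clone_size"] = [int(sizes[u]) for u in ident]
    out["clonal"] = out["clone_size"] >= 2
    return out.drop(columns=["_ident"])


def clonality_contingency(
    clonal_flags: np.ndarray,
    group_of_cell: np.ndarray,
    carrier: str = "carrier",
    control: str = "control",
    yates: bool = True,
) -> dict:
    """2 x 2 clonal/non-clonal x carrier/control table with chi-squared p.

    Returns the table, test statistic/p and per-group clonal percentages.
    """
    clonal_flags = np.asarray(clonal_flags, dtype=bool)
    group_of_cell = np.asarray(group_of_cell, dtype=object)
    cells = {}
    for g in (carrier, control):
        m = group_of_cell == g
        if not m.any():
            raise ValueError(f"group {g} is empty")
        cells[g] = (int((clonal_flags & m).sum()), int((~clonal_flags & m).sum()))
    table = np.array(
        [
            [cells[carrier][0], cells[control][0]],
            [cells[carrier][1], cells[control][1]],
        ],
        dtype=float,
    )
    stat, p = chisq_independence(table, yates=yates)
    pct = {
        g: 100.0 * cells[g][0] / (cells[g][0] + cells[g][1]) for g in (carrier, control)
    }
    return {"table": table, "chi2": stat, "p": p, "clonal_percent": pct}


def clonal_percentages(n_clonal: int, n_nonclonal: int) -> float:
    """Clonal percentage of a group from its two counts."""
    return 100.0 * n_clonal / (n_clonal + n_nonclonal)


def wilcoxon_marker(
    norm_matrix: sp.spmatrix,
    gene_symbols: list[str],
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    marker: str,
) -> float:
    """Two-sided Wilcoxon rank-sum p for a marker between two cell sets.

    Exact distribution when the smaller set has <= 8 values and there are no
    ties; normal approximation with tie correction otherwise.
    """
    cells_a = np.asarray(cells_a)
    cells_b = np.asarray(cells_b)
    if cells_a.dtype == bool:
        cells_a = np.flatnonzero(cells_a)
    if cells_b.dtype == bool:
        cells_b = np.flatnonzero(cells_b)
    if len(cells_a) == 0 or len(cells_b) == 0:
        raise ValueError("both cell sets must be non-empty")
    try:
        row = gene_symbols.index(marker)
    except ValueError:
        raise KeyError(f"marker not in matrix: {marker}") from None
    values = np.asarray(sp.csr_matrix(norm_matrix)[row].todense()).ravel()
    x, y = values[cells_a], values[cells_b]
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def cd8_mask(matrix: ExpressionMatrix, t_cell_mask: np.ndarray) -> np.ndarray:
    """CD8+ T cells: CD8A detected (raw count >= 1) and CD4 undetected."""
    idx = matrix.symbol_index()
    for m in ("CD8A", "CD4"):
        if m not in idx:
            raise ValueError(f"gating gene absent from matrix: {m}")
    cd8a = np.asarray(matrix.counts[idx["CD8A"]].todense()).ravel() >= 1
    cd4 = np.asarray(matrix.counts[idx["CD4"]].todense()).ravel() >= 1
    return np.asarray(t_cell_mask, dtype=bool) & cd8a & ~cd4


def exhaustion_analysis(
    matrix: ExpressionMatrix,
    norm_matrix: sp.spmatrix,
    clonotypes: pd.DataFrame,
    panel: tuple[str, ...] = EXHAUSTION_PANEL,
    cell_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-marker exhaustion statistics joining clonality to expression.

    For each panel marker present in the matrix: cohort ROE with chi-squared
    q (across the panel), clonal-vs-nonclonal Wilcoxon p and carrier-vs-
    control Wilcoxon p.  Missing markers are skipped with a warning.
    """
    import warnings

    barcode_to_col = {b: i for i, b in enumerate(matrix.barcodes)}
    cols = np.array([barcode_to_col[b] for b in clonotypes["barcode"] if b in barcode_to_col])
    matched = clonotypes[clonotypes["barcode"].isin(barcode_to_col)].reset_index(drop=True)
    if len(matched) < len(clonotypes):
        warnings.warn(
            f"{len(clonotypes) - len(matched)} TCR cells have no expression column; dropped"
        )
    if cell_mask is not None:
        keep = np.asarray(cell_mask, dtype=bool)[cols]
        cols, matched = cols[keep], matched[keep].reset_index(drop=True)
    clonal = matched["clonal"].to_numpy(dtype=bool)
    group = matrix.group_of_cell[cols]

    sym_idx = matrix.symbol_index()
    present = [m for m in panel if m in sym_idx]
    missing = [m for m in panel if m not in sym_idx]
    if missing:
        warnings.warn(f"exhaustion markers absent from matrix: {', '.join(missing)}")
    if not present:
        warnings.warn("no exhaustion marker present; empty result")
        return pd.DataFrame(
            columns=["marker", "roe_carrier", "roe_control", "chi2_p", "chi2_q",
                     "p_clonal_vs_nonclonal", "p_carrier_vs_control"]
        )

    tcr_matrix = matrix.subset_cells(cols)
    roe_results = roe_panel(tcr_matrix, tuple(present))
    roe_by_marker = {r.marker: r for r in roe_results}

    rows = []
    for marker in present:
        r = roe_by_marker[marker]
        roe_map = dict(zip(r.groups, np.atleast_1d(r.roe)))
        p_cl = (
            wilcoxon_marker(norm_matrix, matrix.gene_symbols, cols[clonal], cols[~clonal], marker)
            if clonal.any() and (~clonal).any()
            else np.nan
        )
        car, con = group == "carrier", group == "control"
        p_grp = (
            wilcoxon_marker(norm_matrix, matrix.gene_symbols, cols[car], cols[con], marker)
            if car.any() and con.any()
            else np.nan
        )
        rows.append(
            {
                "marker": marker,
                "roe_carrier": roe_map.get("carrier", np.nan),
                "roe_control": roe_map.get("control", np.nan),
                "chi2_p": r.p,
                "chi2_q": r.q,
                "p_clonal_vs_nonclonal": p_cl,
                "p_carrier_vs_control": p_grp,
            }
        )
    return pd.DataFrame(rows)
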