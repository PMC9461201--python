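"""Readers and writers for the standard formats the pipeline touches.

Supported on-disk formats:

* 10x-style count directories: ``matrix.mtx`` (Matrix Market coordinate,
  1-based indices) with ``features.tsv`` / ``genes.tsv`` and ``barcodes.tsv``
  sidecars, optionally gzip-compressed.
* 10x-style ``filtered_contig_annotations.csv`` TCR contig tables.
* GMT gene-set collections.
* TSV/JSON result tables (written by the individual stages).

Internally counts are a ``scipy.sparse`` genes x cells matrix; all indices
are 0-based, the 1-based convention exists only on disk.
"""

from __future__ import annotations

import csv
import gzip
import io as _io
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "TcrChainRecord",
    "FormatError",
    "read_matrix_dir",
    "write_matrix_dir",
    "read_contigs",
    "write_contigs",
    "read_gmt",
    "write_gmt",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


GROUPS = ("carrier", "control")


@dataclass
class ExpressionMatrix:
    """Sparse gene x cell UMI count matrix with cell/gene metadata.

    ``counts`` holds raw non-negative integer counts with genes on rows and
    cells on columns.  ``sample_of_cell`` / ``group_of_cell`` carry the
    cohort design (each cell belongs to one sample, each sample to one of
    the two groups, conventionally ``carrier`` / ``control``).
    """

    counts: sp.spmatrix
    gene_ids: list[str]
    gene_symbols: list[str]
    barcodes: list[str]
    sample_of_cell: np.ndarray
    group_of_cell: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.sample_of_cell = np.asarray(self.sample_of_cell, dtype=object)
        self.group_of_cell = np.asarray(self.group_of_cell, dtype=object)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_symbols) != n_genes:
            raise ValueError("gene annotation length does not match matrix rows")
        if len(self.barcodes) != n_cells:
            raise ValueError("barcode list length does not match matrix columns")
        if len(set(self.barcodes)) != n_cells:
            raise ValueError("barcodes are not unique")
        if self.sample_of_cell.shape != (n_cells,) or self.group_of_cell.shape != (n_cells,):
            raise ValueError("per-cell sample/group labels must have one entry per cell")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.counts.nnz and not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise ValueError("counts must be integral")

    # ---- convenience accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def symbol_index(self) -> dict[str, int]:
        """Map gene symbol -> row, disambiguating duplicate symbols.

        Analysis keys on symbols (marker panels are symbol lists); a
        duplicated symbol is suffixed with its gene id so every row stays
        addressable.
        """
        seen: dict[str, int] = {}
        out: dict[str, int] = {}
        counts: dict[str, int] = {}
        for sym in self.gene_symbols:
            counts[sym] = counts.get(sym, 0) + 1
        for i, sym in enumerate(self.gene_symbols):
            if counts[sym] > 1:
                out[f"{sym}_{self.gene_ids[i]}"] = i
                out.setdefault(sym, i)  # first occurrence keeps the bare symbol
            else:
                out[sym] = i
        del seen
        return out

    def gene_row(self, symbol: str) -> int:
        idx = self.symbol_index()
        if symbol not in idx:
            raise KeyError(f"gene symbol not present: {symbol}")
        return idx[symbol]

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionMatrix(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            gene_symbols=list(self.gene_symbols),
            barcodes=[self.barcodes[i] for i in idx],
            sample_of_cell=self.sample_of_cell[idx],
            group_of_cell=self.group_of_cell[idx],
        )

    def cell_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "sample": self.sample_of_cell,
                "group": self.group_of_cell,
            }
        )


@dataclass(frozen=True)
class TcrChainRecord:
    """One annotated TCR contig (one chain of one cell)."""

    barcode: str
    chain: str  # TRA, TRB or other
    v_gene: str
    j_gene: str
    cdr3_aa: str
    cdr3_nt: str
    umis: int
    productive: bool
    full_length: bool
    is_cell: bool

    def __post_init__(self) -> None:
        if self.umis < 0:
            raise ValueError("umis must be non-negative")
        if self.productive and self.full_length and not self.cdr3_aa:
            raise ValueError("productive full-length contig must carry a CDR3")


# ---------------------------------------------------------------------------
# MTX directories
# ---------------------------------------------------------------------------

def _find_sidecar(path: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = path / (stem + suffix)
            if cand.exists():
                return cand
    raise FormatError(f"missing sidecar file (looked for {', '.join(stems)}) in {path}")


def _open_text(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_matrix_dir(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a 10x-style MTX directory into an :class:`ExpressionMatrix`.

    The directory must contain ``matrix.mtx``, a features/genes table
    (``features.tsv`` or ``genes.tsv``: gene id, symbol) and
    ``barcodes.tsv``; all three may be gzipped.  Sample/group labels are
    taken from a ``cells.tsv`` sidecar when present (columns barcode,
    sample, group) and default to ``sample='sample'``, ``group='control'``
    otherwise.
    """
    path = Path(path)
    mtx = _find_sidecar(path, ["matrix.mtx"])
    features = _find_sidecar(path, ["features.tsv", "genes.tsv"])
    barcodes_f = _find_sidecar(path, ["barcodes.tsv"])

    with _open_text(mtx, "rb") as fh:
        counts = scipy.io.mmread(fh)
    counts = sp.csr_matrix(counts)

    feat = pd.read_csv(features, sep="\t", header=None, dtype=str)
    gene_ids = feat[0].tolist()
    gene_symbols = (feat[1] if feat.shape[1] > 1 else feat[0]).tolist()
    barcodes = pd.read_csv(barcodes_f, sep="\t", header=None, dtype=str)[0].tolist()

    if counts.shape != (len(gene_ids), len(barcodes)):
        raise FormatError(
            f"matrix dimensions {counts.shape} do not match sidecars "
            f"({len(gene_ids)} genes, {len(barcodes)} barcodes) in {path}"
        )

    try:
        cells_f = _find_sidecar(path, ["cells.tsv"])
        cells = pd.read_csv(cells_f, sep="\t", dtype=str)
        cells = cells.set_index("barcode").reindex(barcodes)
        sample = cells["sample"].to_numpy(dtype=object)
        group = cells["group"].to_numpy(dtype=object)
    except FormatError:
        sample = np.array(["sample"] * len(barcodes), dtype=object)
        group = np.array(["control"] * len(barcodes), dtype=object)

    return ExpressionMatrix(counts, gene_ids, gene_symbols, barcodes, sample, group)


def write_matrix_dir(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write an :class:`ExpressionMatrix` as an uncompressed MTX directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(matrix.counts), field="integer")
    pd.DataFrame({"id": matrix.gene_ids, "symbol": matrix.gene_symbols}).to_csv(
        path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(matrix.barcodes).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    matrix.cell_table().to_csv(path / "cells.tsv", sep="\t", index=False)


def concat_matrices(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate per-sample matrices sharing the same gene space."""
    first = matrices[0]
    for m in matrices[1:]:
        if m.gene_ids != first.gene_ids:
            raise ValueError("matrices do not share a gene space")
    return ExpressionMatrix(
        counts=sp.hstack([m.counts for m in matrices], format="csr"),
        gene_ids=list(first.gene_ids),
        gene_symbols=list(first.gene_symbols),
        barcodes=[b for m in matrices for b in m.barcodes],
        sample_of_cell=np.concatenate([m.sample_of_cell for m in matrices]),
        group_of_cell=np.concatenate([m.group_of_cell for m in matrices]),
    )


# ---------------------------------------------------------------------------
# Contig CSV
# ---------------------------------------------------------------------------

_CONTIG_COLUMNS = [
    "barcode",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3",
    "cdr3_nt",
    "umis",
    "productive",
    "full_length",
    "is_cell",
]


def _parse_bool(value: str, column: str, line: int) -> bool:
    v = str(value).strip().lower()
    if v in ("true", "t", "1"):
        return True
    if v in ("false", "f", "0", "none", ""):
        return False
    raise FormatError(f"unparseable boolean {value!r} in column {column}, row {line}")


def read_contigs(path: str | os.PathLike) -> list[TcrChainRecord]:
    """Read a 10x-style ``filtered_contig_annotations.csv``.

    Chains other than TRA/TRB (e.g. IGH from ambient B-cell material) are
    retained with ``chain='other'``; downstream pairing drops them.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"empty contig file: {path}")
        missing = [c for c in _CONTIG_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"contig file {path} missing required column(s): {', '.join(missing)}")
        records = []
        for i, row in enumerate(reader, start=2):
            chain = row["chain"].strip()
            if chain not in ("TRA", "TRB"):
                chain = "other"
            records.append(
                TcrChainRecord(
                    barcode=row["barcode"].strip(),
                    chain=chain,
                    v_gene=row["v_gene"].strip(),
                    j_gene=row["j_gene"].strip(),
                    cdr3_aa=row["cdr3"].strip(),
                    cdr3_nt=row["cdr3_nt"].strip(),
                    umis=int(row["umis"]),
                    productive=_parse_bool(row["productive"], "productive", i),
                    full_length=_parse_bool(row["full_length"], "full_length", i),
                    is_cell=_parse_bool(row["is_cell"], "is_cell", i),
                )
            )
    return records


def write_contigs(records: Iterable[TcrChainRecord], path: str | os.PathLike) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CONTIG_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.barcode,
                    r.chain,
                    r.v_gene,
                    r.j_gene,
                    r.cdr3_aa,
                    r.cdr3_nt,
                    r.umis,
                    str(r.productive),
                    str(r.full_length),
                    str(r.is_cell),
                ]
            )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT collection: name, description, then member genes.

    Duplicate members within one line are dropped, first occurrence wins;
    member order is otherwise preserved.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} has fewer than 3 fields")
            name = fields[0]
            members: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    members.append(g)
                    seen.add(g)
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")
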