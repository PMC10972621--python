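"""Core data model: count matrices, cell/gene tables, gene sets, normalization.

The in-memory convention throughout the package:

* counts — ``scipy.sparse`` matrix (or dense ndarray), genes x cells, raw
  non-negative integer UMI counts;
* cells — :class:`pandas.DataFrame` with one row per cell (columns
  ``cell_id``, ``sample_id``, ``condition``, ``cell_type``, ``doublet_score``,
  ``total_umis``; the last four optional);
* genes — :class:`pandas.DataFrame` with one row per gene (columns
  ``gene_id``, ``symbol``, optional ``chromosome``, ``start``, ``chrom_rank``).

On disk the bundle is the standard 10x-style triplet: MatrixMarket ``.mtx``
plus two tab-delimited tables. Gene sets travel as GMT text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

CONDITIONS = ("metastatic", "nonmetastatic", "primary")

CELL_COLUMNS = ("cell_id", "sample_id", "condition", "cell_type",
                "doublet_score", "total_umis")
GENE_COLUMNS = ("gene_id", "symbol", "chromosome", "start", "chrom_rank")


class BundleError(ValueError):
    """Malformed matrix bundle (bad header, dimension mismatch, duplicates)."""


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (one GMT row)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.genes)


def validate_cell_table(cells: pd.DataFrame) -> None:
    if "cell_id" not in cells.columns:
        raise BundleError("cell table lacks a cell_id column")
    if cells["cell_id"].duplicated().any():
        dup = cells["cell_id"][cells["cell_id"].duplicated()].iloc[0]
        raise BundleError(f"duplicate cell identifier: {dup!r}")


def validate_gene_table(genes: pd.DataFrame) -> None:
    if "gene_id" not in genes.columns:
        raise BundleError("gene table lacks a gene_id column")
    if genes["gene_id"].duplicated().any():
        dup = genes["gene_id"][genes["gene_id"].duplicated()].iloc[0]
        raise BundleError(f"duplicate gene identifier: {dup!r}")


def _as_int_csr(matrix) -> sp.csr_matrix:
    m = sp.csr_matrix(matrix)
    if m.nnz and m.data.min() < 0:
        raise BundleError("count matrix has negative entries")
    if not np.issubdtype(m.dtype, np.integer):
        if m.nnz and not np.allclose(m.data, np.round(m.data)):
            raise BundleError("count matrix has non-integral entries")
        m = m.astype(np.int64)
    return m


def read_mtx_bundle(matrix_path, genes_path, cells_path):
    """Read a MatrixMarket + gene-table + cell-table triplet.

    Returns ``(counts, genes, cells)`` with counts as a genes x cells CSR
    integer matrix. Raises :class:`BundleError` on malformed headers,
    dimension mismatches or duplicate identifiers.
    """
    try:
        counts = scipy.io.mmread(str(matrix_path))
    except ValueError as exc:
        raise BundleError(f"malformed MatrixMarket file {matrix_path}: {exc}") from exc
    counts = _as_int_csr(counts)
    genes = pd.read_csv(genes_path, sep="\t", dtype={"gene_id": str, "symbol": str})
    cells = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str, "sample_id": str})
    validate_gene_table(genes)
    validate_cell_table(cells)
    if counts.shape[0] != len(genes):
        raise BundleError(
            f"matrix declares {counts.shape[0]} genes but gene table has {len(genes)} rows")
    if counts.shape[1] != len(cells):
        raise BundleError(
            f"matrix declares {counts.shape[1]} cells but cell table has {len(cells)} rows")
    for col in CELL_COLUMNS:
        if col not in cells.columns:
            cells[col] = pd.NA
    if "symbol" not in genes.columns:
        genes["symbol"] = genes["gene_id"]
    return counts, genes.reset_index(drop=True), cells.reset_index(drop=True)


def write_mtx_bundle(outdir, counts, genes: pd.DataFrame, cells: pd.DataFrame,
                     prefix: str = "") -> dict[str, Path]:
    """Write the triplet bundle; round-trips bit-exactly on integer data."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    validate_gene_table(genes)
    validate_cell_table(cells)
    counts = _as_int_csr(counts)
    if counts.shape != (len(genes), len(cells)):
        raise BundleError(
            f"matrix shape {counts.shape} does not match tables "
            f"({len(genes)} genes, {len(cells)} cells)")
    paths = {
        "matrix": outdir / f"{prefix}matrix.mtx",
        "genes": outdir / f"{prefix}genes.tsv",
        "cells": outdir / f"{prefix}cells.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(counts))
    genes.to_csv(paths["genes"], sep="\t", index=False)
    cells.to_csv(paths["cells"], sep="\t", index=False)
    return paths


def read_gmt(path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
        sets.append(GeneSet(name=parts[0], description=parts[1],
                            genes=tuple(dict.fromkeys(g for g in parts[2:] if g))))
    return sets


def write_gmt(path, sets) -> None:
    lines = ["\t".join([s.name, s.description or "na", *s.genes]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class NormalizedMatrix:
    """Dense genes x cells matrix of library-size-normalized expression.

    ``values[i, j] = log1p(counts[i, j] / total_j * scale)`` when ``log`` is
    set, otherwise the scaled linear value. Rows are addressable either by
    gene_id or by symbol; duplicate symbols resolve to the row with the
    larger total count (a warning is logged once per collision).
    """

    values: np.ndarray
    gene_ids: pd.Index
    symbols: np.ndarray
    cell_ids: pd.Index
    scale: float
    log: bool
    _symbol_to_row: dict = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match gene/cell indices")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized matrix contains non-finite entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def _symbol_map(self) -> dict:
        if self._symbol_to_row is None:
            totals = self.values.sum(axis=1)
            mapping: dict[str, int] = {}
            for i, s in enumerate(self.symbols):
                if s in mapping:
                    logger.warning("duplicate symbol %s: keeping higher-total row", s)
                    if totals[i] <= totals[mapping[s]]:
                        continue
                mapping[s] = i
            object.__setattr__(self, "_symbol_to_row", mapping)
        return self._symbol_to_row

    def rows_for_symbols(self, symbols) -> tuple[np.ndarray, list[str]]:
        """Row indices for the given symbols plus the list of absent ones."""
        mapping = self._symbol_map()
        found, missing = [], []
        for s in symbols:
            if s in mapping:
                found.append(mapping[s])
            else:
                missing.append(s)
        return np.asarray(found, dtype=int), missing

    def subset_cells(self, mask_or_ids) -> "NormalizedMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            idx = self.cell_ids.get_indexer(pd.Index(mask_or_ids))
            if (idx < 0).any():
                raise KeyError("unknown cell identifiers in subset request")
        return NormalizedMatrix(self.values[:, idx], self.gene_ids,
                                self.symbols, self.cell_ids[idx],
                                self.scale, self.log)


def normalize(counts, genes: pd.DataFrame, cells: pd.DataFrame,
              scale: float = 1e4, log_transform: bool = True) -> NormalizedMatrix:
    """Library-size normalization: counts / cell_total * scale, then log1p.

    A cell with zero total counts cannot be normalized; an explicit error
    names the offending cell.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    dense = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    if dense.shape != (len(genes), len(cells)):
        raise BundleError("counts shape does not match gene/cell tables")
    totals = dense.sum(axis=0)
    if (totals == 0).any():
        bad = cells["cell_id"].iloc[int(np.argmax(totals == 0))]
        raise ValueError(f"cell {bad!r} has zero total counts and cannot be normalized")
    vals = dense / totals * scale
    if log_transform:
        vals = np.log1p(vals)
    return NormalizedMatrix(
        values=vals,
        gene_ids=pd.Index(genes["gene_id"].astype(str)),
        symbols=genes.get("symbol", genes["gene_id"]).astype(str).to_numpy(),
        cell_ids=pd.Index(cells["cell_id"].astype(str)),
        scale=float(scale),
        log=bool(log_transform),
    )


def total_umis(counts) -> np.ndarray:
    """Per-cell total UMI counts (column sums)."""
    if sp.issparse(counts):
        return np.asarray(counts.sum(axis=0)).ravel().astype(np.int64)
    return np.asarray(counts).sum(axis=0).astype(np.int64)


def order_genes_by_position(genes: pd.DataFrame) -> pd.DataFrame:
    """Sort genes by (chromosome, start) and assign within-chromosome ranks."""
    if "chromosome" not in genes.columns or "start" not in genes.columns:
        raise ValueError("gene table needs chromosome and start columns for ordering")
    out = genes.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
    out["chrom_rank"] = out.groupby("chromosome").cumcount() + 1
    return out
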