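"""Normalization and maternal/zygotic decomposition of labeled UMI counts.

Per cell, total expression is the standard library-size normalization
(counts over cell total, times a scale factor of 10,000, log1p, natural
log).  The labeled fraction (NTR) splits each gene's UMIs into maternal
(UMI * (1 - NTR)) and zygotic (UMI * NTR) effective counts before the same
transform, so that on the linear (expm1) scale maternal + zygotic = total.

Pseudo-bulk profiles normalize group-level expression to relative abundance
(times 10,000), split by the group-level NTR, log2-transform and floor at -4.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from .datatypes import FLOOR_LOG2, CellTable, ExpressionTriplet


def filter_cells_genes(
    table: CellTable,
    min_genes_per_cell: int = 500,
    min_umi_per_cell_per_gene: int = 3,
    min_total_umi_per_gene: int = 50,
) -> tuple[CellTable, sparse.spmatrix, np.ndarray]:
    """Drop shallow cells and build the single-cell usability mask.

    Cells detecting fewer than ``min_genes_per_cell`` genes are removed.  The
    returned (gene x cell) boolean mask marks entries with at least
    ``min_umi_per_cell_per_gene`` UMIs belonging to genes with at least
    ``min_total_umi_per_gene`` UMIs overall; it gates single-cell-level
    analyses only (pseudo-bulk aggregation uses all counts).
    """
    if min(min_genes_per_cell, min_umi_per_cell_per_gene, min_total_umi_per_gene) < 0:
        raise ValueError("thresholds must be non-negative")
    genes_per_cell = np.asarray((table.counts > 0).sum(axis=0)).ravel()
    keep = genes_per_cell >= min_genes_per_cell
    if not keep.any():
        raise ValueError("no cells pass the gene-detection threshold")
    filtered = table.subset_cells(keep)
    gene_totals = np.asarray(filtered.counts.sum(axis=1)).ravel()
    gene_ok = gene_totals >= min_total_umi_per_gene
    if min_umi_per_cell_per_gene > 0:
        entry_ok = sparse.csr_matrix(filtered.counts >= min_umi_per_cell_per_gene)
    else:
        entry_ok = sparse.csr_matrix(np.ones(filtered.counts.shape, dtype=bool))
    mask = entry_ok.multiply(gene_ok[:, None]).astype(bool)
    return filtered, sparse.csr_matrix(mask), gene_ok


def _cell_totals(table: CellTable) -> np.ndarray:
    totals = np.asarray(table.counts.sum(axis=0)).ravel().astype(float)
    if np.any(totals == 0):
        raise ValueError("cell with zero total UMI")
    return totals


def normalize_cell_expression(table: CellTable, scale: float = 1e4) -> pd.DataFrame:
    """Per-cell total expression: log1p(UMI / cell total * scale), natural log."""
    totals = _cell_totals(table)
    dense = table.counts.toarray().astype(float)
    return pd.DataFrame(np.log1p(dense / totals[None, :] * scale),
                        index=table.genes, columns=table.meta.index)


def decompose_maternal_zygotic(table: CellTable, scale: float = 1e4) -> ExpressionTriplet:
    """Split per-cell expression into maternal and zygotic components.

    Entries without a labeled-fraction estimate are NaN in the maternal and
    zygotic frames (absent, never imputed to zero).
    """
    totals = _cell_totals(table)
    dense = table.counts.toarray().astype(float)
    scaled = dense / totals[None, :] * scale
    total = np.log1p(scaled)
    maternal = np.log1p(scaled * (1.0 - table.ntr))
    zygotic = np.log1p(scaled * table.ntr)
    cols = table.meta.index
    return ExpressionTriplet(
        total=pd.DataFrame(total, index=table.genes, columns=cols),
        maternal=pd.DataFrame(maternal, index=table.genes, columns=cols),
        zygotic=pd.DataFrame(zygotic, index=table.genes, columns=cols),
        log_base="log1p",
    )


def aggregate_pseudobulk(
    table: CellTable, grouping, min_umi_for_ntr: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate counts and count-weighted labeled fractions per cell group.

    Returns (gene x group summed counts, gene x group NTR).  The group NTR is
    the UMI-weighted mean of per-cell NTRs over cells where the gene is
    detected and an estimate exists; NaN where no information is available.
    """
    grouping = pd.Series(np.asarray(grouping), index=table.meta.index)
    groups = list(dict.fromkeys(grouping))
    counts = table.counts.toarray().astype(float)
    expr = {}
    ntr = {}
    for g in groups:
        cols = np.asarray(grouping == g)
        if not cols.any():
            raise ValueError(f"empty group {g!r}")
        sub = counts[:, cols]
        sub_ntr = table.ntr[:, cols]
        expr[g] = sub.sum(axis=1)
        w = np.where(np.isfinite(sub_ntr) & (sub >= min_umi_for_ntr), sub, 0.0)
        wsum = w.sum(axis=1)
        with np.errstate(invalid="ignore"):
            ntr[g] = np.where(wsum > 0, np.nansum(w * np.nan_to_num(sub_ntr), axis=1)
                              / np.where(wsum > 0, wsum, 1.0), np.nan)
    return (pd.DataFrame(expr, index=table.genes), pd.DataFrame(ntr, index=table.genes))


def pseudobulk_expression(
    expression: pd.DataFrame,
    ntr: pd.DataFrame,
    scale: float = 1e4,
    floor: float = FLOOR_LOG2,
) -> ExpressionTriplet:
    """Group-level decomposition: normalize, split by group NTR, log2, floor.

    ``expression`` holds gene x group linear expression (e.g. summed counts);
    ``ntr`` the matching group-level labeled fractions.
    """
    col_sums = expression.sum(axis=0)
    if (col_sums == 0).any():
        raise ValueError("group with zero total expression")
    total_lin = expression / col_sums * scale
    ntr = ntr.reindex(index=expression.index, columns=expression.columns)
    with np.errstate(invalid="ignore"):
        if ((ntr < 0) | (ntr > 1)).any().any():
            raise ValueError("ntr values outside [0, 1]")
    maternal_lin = total_lin * (1.0 - ntr)
    zygotic_lin = total_lin * ntr

    def _log2_floor(df: pd.DataFrame) -> pd.DataFrame:
        with np.errstate(divide="ignore"):
            vals = np.log2(df.to_numpy(dtype=float))
        vals = np.where(np.isnan(df.to_numpy(dtype=float)), np.nan, np.maximum(vals, floor))
        return pd.DataFrame(vals, index=df.index, columns=df.columns)

    return ExpressionTriplet(
        total=_log2_floor(total_lin),
        maternal=_log2_floor(maternal_lin),
        zygotic=_log2_floor(zygotic_lin),
        log_base="log2",
    )


def log2_cpm_pseudobulk(
    table_a: CellTable, table_b: CellTable, floor: float = FLOOR_LOG2
) -> pd.DataFrame:
    """Paired per-gene log2 counts-per-million over two whole tables."""
    if not table_a.genes.equals(table_b.genes):
        raise ValueError("tables must share a gene universe")
    out = {}
    for name, tbl in (("a", table_a), ("b", table_b)):
        totals = np.asarray(tbl.counts.sum(axis=1)).ravel().astype(float)
        grand = totals.sum()
        with np.errstate(divide="ignore"):
            vals = np.log2(totals / grand * 1e6)
        out[name] = np.maximum(vals, floor)
    return pd.DataFrame(out, index=table_a.genes)
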