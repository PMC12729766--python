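"""Quality control, CP10k + log1p normalization and HVG selection.

The pipeline mirrors the standard single-cell recipe: filter cells by expressed
gene count and mitochondrial fraction, drop rarely expressed genes, scale each
cell to a total of 10,000 counts, apply ln(1+x), then keep the most variable
genes as the model's feature set.
"""

from __future__ import annotations

import numpy as np

from .errors import EmptyResultError, ValidationError
from .matrix import (
    SCALE_COUNTS,
    SCALE_LOGNORM,
    ExpressionMatrix,
    QCReport,
    QCThresholds,
)

CP10K_TOTAL = 10_000.0


def qc_filter(m: ExpressionMatrix,
              t: QCThresholds = QCThresholds()) -> tuple[ExpressionMatrix, QCReport]:
    """Remove low-quality cells, then genes expressed in too few cells.

    Cells are dropped when their expressed-gene count falls outside
    ``[min_genes_per_cell, max_genes_per_cell]`` or their mitochondrial count
    fraction exceeds ``max_mito_fraction`` (mito genes matched by id prefix).
    The gene filter runs on the surviving cells.
    """
    if m.scale_tag != SCALE_COUNTS:
        raise ValidationError("qc_filter requires a raw count matrix")

    genes_per_cell = np.count_nonzero(m.values, axis=1)
    low = genes_per_cell < t.min_genes_per_cell
    high = genes_per_cell > t.max_genes_per_cell

    mito_mask = np.array([g.startswith(t.mito_prefix) for g in m.gene_ids])
    totals = m.values.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, m.values[:, mito_mask].sum(axis=1) / totals, 0.0
        )
    mito_bad = mito_frac > t.max_mito_fraction

    keep_cells = ~(low | high | mito_bad)
    if not keep_cells.any():
        raise EmptyResultError("QC removed every cell; relax the thresholds")

    filtered = m.subset_cells(np.flatnonzero(keep_cells))

    cells_per_gene = np.count_nonzero(filtered.values, axis=0)
    keep_genes = cells_per_gene >= t.min_cells_per_gene
    if not keep_genes.any():
        raise EmptyResultError("QC removed every gene; relax min_cells_per_gene")
    filtered = filtered.subset_genes(np.flatnonzero(keep_genes))

    report = QCReport(
        n_cells_in=m.n_cells,
        n_genes_in=m.n_genes,
        # removal reasons are attributed in order: low, then high, then mito
        cells_removed_low_genes=int(low.sum()),
        cells_removed_high_genes=int((high & ~low).sum()),
        cells_removed_mito=int((mito_bad & ~low & ~high).sum()),
        genes_removed_low_cells=int((~keep_genes).sum()),
    )
    return filtered, report


def normalize_log(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell to 10,000 total counts, then apply ln(1+x)."""
    if m.scale_tag != SCALE_COUNTS:
        raise ValidationError("normalize_log expects raw counts")
    totals = m.values.sum(axis=1)
    if np.any(totals <= 0):
        raise ValidationError(
            "cells with zero total counts present; run qc_filter first"
        )
    cp10k = m.values * (CP10K_TOTAL / totals)[:, None]
    return m.with_values(np.log1p(cp10k), scale_tag=SCALE_LOGNORM)


def hvg_statistic(values: np.ndarray) -> np.ndarray:
    """Per-gene dispersion statistic: variance of log-normalized expression."""
    return values.var(axis=0, ddof=0)


def select_hvg(m: ExpressionMatrix, n_top: int = 5000) -> ExpressionMatrix:
    """Keep the ``n_top`` most variable genes, preserving original column order.

    Ranking is by variance of the log-normalized values; ties break toward the
    higher-mean gene, then lexicographically smaller gene id, so the selected
    set is deterministic.
    """
    if m.scale_tag != SCALE_LOGNORM:
        raise ValidationError("select_hvg expects cp10k_log1p values")
    if n_top <= 0:
        raise ValidationError("n_top must be >= 1")

    if n_top >= m.n_genes:
        return m.copy()

    var = hvg_statistic(m.values)
    mean = m.values.mean(axis=0)
    order = sorted(
        range(m.n_genes),
        key=lambda j: (-var[j], -mean[j], m.gene_ids[j]),
    )
    selected = sorted(order[:n_top])  # restore original column order
    return m.subset_genes(selected)
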