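"""Cell x gene expression container used by every stage of the pipeline.

The matrix is always cells-as-rows in memory. ``scale_tag`` records whether the
values are raw counts or CP10k + log1p normalized data, so downstream stages can
enforce their preconditions (the degradation simulator and the repair models
operate on the normalized scale only).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .errors import LookupError_, ShapeError, ValidationError

SCALE_COUNTS = "counts"
SCALE_LOGNORM = "cp10k_log1p"
_VALID_SCALES = (SCALE_COUNTS, SCALE_LOGNORM)


@dataclass
class ExpressionMatrix:
    """Dense cells x genes expression values with aligned metadata.

    Parameters
    ----------
    values
        2-D float array, cells as rows.
    gene_ids
        Unique gene identifiers, one per column.
    cell_ids
        Cell barcodes/identifiers, one per row.
    gene_lengths
        Optional transcript lengths in bases, aligned to ``gene_ids``. Required
        before simulating length-dependent degradation.
    cell_labels
        Optional per-cell type annotations.
    scale_tag
        ``"counts"`` for raw counts, ``"cp10k_log1p"`` after normalization.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    gene_lengths: Optional[np.ndarray] = None
    cell_labels: Optional[list[str]] = None
    scale_tag: str = SCALE_COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError("values must be a 2-D cells x genes array")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_cells, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ShapeError(
                f"{n_genes} gene columns but {len(self.gene_ids)} gene ids"
            )
        if len(self.cell_ids) != n_cells:
            raise ShapeError(
                f"{n_cells} cell rows but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("gene_ids must be unique")
        if self.scale_tag not in _VALID_SCALES:
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        if self.scale_tag == SCALE_COUNTS and np.any(self.values < 0):
            raise ValidationError("count matrices must be nonnegative")
        if self.gene_lengths is not None:
            self.gene_lengths = np.asarray(self.gene_lengths, dtype=np.float64)
            if self.gene_lengths.shape != (n_genes,):
                raise ShapeError("gene_lengths must align with gene_ids")
            if np.any(self.gene_lengths <= 0):
                raise ValidationError("gene_lengths must be strictly positive")
        if self.cell_labels is not None:
            self.cell_labels = [str(x) for x in self.cell_labels]
            if len(self.cell_labels) != n_cells:
                raise ShapeError("cell_labels must align with cell_ids")

    # -- basic introspection -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise LookupError_(f"gene id {gene_id!r} not in matrix") from None

    def gene_column(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene_id)]

    # -- subsetting ----------------------------------------------------------

    def subset_cells(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            values=self.values[idx].copy(),
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_labels=(
                [self.cell_labels[i] for i in idx] if self.cell_labels else None
            ),
        )

    def subset_genes(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            values=self.values[:, idx].copy(),
            gene_ids=[self.gene_ids[i] for i in idx],
            gene_lengths=(
                self.gene_lengths[idx] if self.gene_lengths is not None else None
            ),
        )

    def copy(self) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values.copy(),
            gene_ids=list(self.gene_ids),
            cell_ids=list(self.cell_ids),
            gene_lengths=(
                self.gene_lengths.copy() if self.gene_lengths is not None else None
            ),
            cell_labels=list(self.cell_labels) if self.cell_labels else None,
        )

    def with_values(self, values: np.ndarray, scale_tag: Optional[str] = None
                    ) -> "ExpressionMatrix":
        """Same metadata, new value block (shape must match)."""
        values = np.asarray(values, dtype=np.float64)
        if values.shape != self.values.shape:
            raise ShapeError("replacement values must keep the matrix shape")
        return replace(self, values=values,
                       scale_tag=scale_tag or self.scale_tag)

    # -- interop -------------------------------------------------------------

    def to_anndata(self):
        """Export to :class:`anndata.AnnData` (lengths in .var, tag in .uns)."""
        import anndata
        import pandas as pd

        var = pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        if self.gene_lengths is not None:
            var["gene_length"] = self.gene_lengths
        obs = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        if self.cell_labels is not None:
            obs["cell_type"] = self.cell_labels
        adata = anndata.AnnData(X=self.values.copy(), obs=obs, var=var)
        adata.uns["scale_tag"] = self.scale_tag
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "ExpressionMatrix":
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = np.asarray(X.todense())
        lengths = None
        if "gene_length" in adata.var:
            lengths = np.asarray(adata.var["gene_length"], dtype=float)
        labels = None
        if "cell_type" in adata.obs:
            labels = [str(x) for x in adata.obs["cell_type"]]
        return cls(
            values=np.asarray(X, dtype=np.float64),
            gene_ids=[str(g) for g in adata.var_names],
            cell_ids=[str(c) for c in adata.obs_names],
            gene_lengths=lengths,
            cell_labels=labels,
            scale_tag=str(adata.uns.get("scale_tag", SCALE_COUNTS)),
        )


@dataclass(frozen=True)
class QCThresholds:
    """Cell/gene quality-control cutoffs.

    Defaults are permissive conventions, not published values; tune per dataset.
    """

    min_genes_per_cell: int = 1
    max_genes_per_cell: int = 10**9
    max_mito_fraction: float = 1.0
    min_cells_per_gene: int = 1
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell > self.max_genes_per_cell:
            raise ValidationError("min_genes_per_cell > max_genes_per_cell")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValidationError("max_mito_fraction must be in [0, 1]")


@dataclass(frozen=True)
class QCReport:
    """Counts of what qc_filter removed and why."""

    n_cells_in: int
    n_genes_in: int
    cells_removed_low_genes: int = 0
    cells_removed_high_genes: int = 0
    cells_removed_mito: int = 0
    genes_removed_low_cells: int = 0

    @property
    def n_cells_out(self) -> int:
        return (self.n_cells_in - self.cells_removed_low_genes
                - self.cells_removed_high_genes - self.cells_removed_mito)

    @property
    def n_genes_out(self) -> int:
        return self.n_genes_in - self.genes_removed_low_cells
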