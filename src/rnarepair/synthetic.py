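"""Synthetic single-cell-like datasets with known ground truth.

Counts follow a gamma-Poisson (negative binomial) law, the standard
overdispersed model for scRNA-seq, with cells grouped into discrete types and a
configurable number of marker genes per type whose mean is elevated by a known
log fold-change within their own type. Transcript lengths are log-normal,
giving the length-dependent degradation model realistic variation. A paired
surface-protein panel provides an RNA-independent readout for orthogonal
validation: each protein is a monotone (affine) transform of its paired gene's
log-normalized expression plus Gaussian measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd

from .errors import LookupError_, ValidationError
from .matrix import SCALE_COUNTS, ExpressionMatrix
from .preprocess import normalize_log


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the simulated dataset.

    ``dispersion`` is the negative-binomial overdispersion phi, so each count
    has variance mu + phi * mu^2. ``marker_log_fc`` is the natural-log
    fold-change of a marker gene's mean inside its own cell type.
    """

    n_cells: int = 2000
    n_genes: int = 500
    n_types: int = 4
    markers_per_type: int = 10
    marker_log_fc: float = log(4.0)
    base_mean: float = 2.0
    dispersion: float = 0.5
    length_log_mean: float = 7.5   # median transcript ~ 1.8 kb
    length_log_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ValidationError("n_types must be >= 1")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValidationError(
                "markers_per_type * n_types exceeds n_genes"
            )
        for name in ("marker_log_fc", "base_mean", "dispersion",
                     "length_log_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("n_cells", "n_genes", "markers_per_type"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")


@dataclass
class ProteinPanel:
    """Paired per-cell surface-protein measurements.

    ``pairs`` maps each protein to the gene whose product it reports on;
    ``protein_values`` is cells x proteins, row-aligned with the RNA matrix.
    """

    protein_values: np.ndarray
    protein_names: list[str]
    pairs: list[tuple[str, str]]  # (protein name, gene id)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.protein_values = np.atleast_2d(
            np.asarray(self.protein_values, dtype=np.float64)
        )
        if self.protein_values.shape[1] != len(self.protein_names):
            raise ValidationError("protein_values columns must match names")


def generate_truth(spec: SyntheticSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw the ground-truth count matrix and its marker table.

    Returns the counts (with cell-type labels and gene lengths attached) and a
    DataFrame with columns ``gene_id`` and ``cell_type`` listing the planted
    markers.
    """
    rng = np.random.default_rng(spec.seed)

    gene_ids = [f"G{j:05d}" for j in range(spec.n_genes)]
    cell_ids = [f"C{i:05d}" for i in range(spec.n_cells)]

    # balanced type assignment, then shuffled so order carries no signal
    types = [f"type{k}" for k in range(spec.n_types)]
    labels = np.array(
        [types[i % spec.n_types] for i in range(spec.n_cells)]
    )
    rng.shuffle(labels)

    # per-gene baseline means vary log-normally around base_mean
    base = spec.base_mean * rng.lognormal(mean=0.0, sigma=0.5,
                                          size=spec.n_genes)

    # plant markers: gene block k gets exp(marker_log_fc) in type k
    marker_rows = []
    log_fc = np.zeros((spec.n_types, spec.n_genes))
    g = 0
    for k, t in enumerate(types):
        for _ in range(spec.markers_per_type):
            if spec.n_types > 1:
                log_fc[k, g] = spec.marker_log_fc
                marker_rows.append({"gene_id": gene_ids[g], "cell_type": t})
            g += 1
    marker_table = pd.DataFrame(marker_rows, columns=["gene_id", "cell_type"])

    type_index = np.array([types.index(t) for t in labels])
    mu = base[None, :] * np.exp(log_fc[type_index])  # cells x genes

    # gamma-Poisson mixture: Var = mu + dispersion * mu^2
    shape = 1.0 / spec.dispersion
    lam = rng.gamma(shape=shape, scale=mu * spec.dispersion)
    counts = rng.poisson(lam).astype(np.float64)

    lengths = rng.lognormal(mean=spec.length_log_mean,
                            sigma=spec.length_log_sd, size=spec.n_genes)

    matrix = ExpressionMatrix(
        values=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        gene_lengths=lengths,
        cell_labels=list(labels),
        scale_tag=SCALE_COUNTS,
    )
    return matrix, marker_table


def select_panel_genes(marker_table: pd.DataFrame,
                       n_pairs: int = 6) -> list[tuple[str, str]]:
    """Pick panel genes cycling across cell types, like a real immune panel.

    Returns (protein name, gene id) pairs where protein names are derived
    from the gene ids. Raises if the marker table cannot supply n_pairs.
    """
    by_type: dict[str, list[str]] = {
        t: list(sub["gene_id"]) for t, sub in marker_table.groupby("cell_type")
    }
    if not by_type or sum(len(v) for v in by_type.values()) < n_pairs:
        raise ValidationError(
            f"marker table has too few genes for a {n_pairs}-pair panel"
        )
    types = sorted(by_type)
    pairs: list[tuple[str, str]] = []
    i = 0
    while len(pairs) < n_pairs:
        t = types[i % len(types)]
        if by_type[t]:
            g = by_type[t].pop(0)
            pairs.append((f"P_{g}", g))
        i += 1
    return pairs


def generate_protein_panel(
    truth: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    noise_sd: float = 0.3,
    seed: int = 0,
) -> ProteinPanel:
    """Simulate a surface-protein readout paired with ``truth``.

    Each protein is an affine transform of its gene's log-normalized expression
    plus N(0, noise_sd^2) measurement noise, so at noise_sd=0 the Spearman
    correlation with the paired gene is exactly 1.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    missing = [g for _, g in pairs if g not in truth.gene_ids]
    if missing:
        raise LookupError_(f"paired gene ids not in matrix: {missing}")

    if truth.scale_tag == SCALE_COUNTS:
        lognorm = normalize_log(truth)
    else:
        lognorm = truth

    rng = np.random.default_rng(seed)
    n_cells = truth.n_cells
    if not pairs:
        return ProteinPanel(
            protein_values=np.zeros((n_cells, 0)),
            protein_names=[],
            pairs=[],
            cell_ids=list(truth.cell_ids),
        )

    cols = []
    for protein, gene in pairs:
        expr = lognorm.gene_column(gene)
        # affine link (scale 1.5, offset 1) keeps the transform monotone
        cols.append(1.5 * expr + 1.0 + rng.normal(0.0, noise_sd, size=n_cells))
    return ProteinPanel(
        protein_values=np.column_stack(cols),
        protein_names=[p for p, _ in pairs],
        pairs=list(pairs),
        cell_ids=list(truth.cell_ids),
    )
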