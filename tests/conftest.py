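"""Shared fixtures.

The expensive end-to-end experiment (synthetic data -> degrade -> train the
reduced Transformer -> repair held-out cells) runs once per session and is
shared by every test that needs a trained model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pytest

from rnarepair import (
    DegradationParams,
    ExpressionMatrix,
    RepairModelConfig,
    SyntheticSpec,
    TrainConfig,
    build_model,
    degrade,
    generate_protein_panel,
    generate_truth,
    normalize_log,
    qc_filter,
    select_hvg,
    split_dataset,
    train,
)
from rnarepair.synthetic import select_panel_genes


@pytest.fixture(scope="session")
def small_truth():
    """2000 x 500 clustered synthetic counts with planted markers."""
    spec = SyntheticSpec(n_cells=2000, n_genes=500, n_types=4,
                         markers_per_type=10, seed=42)
    truth, markers = generate_truth(spec)
    return truth, markers


@pytest.fixture(scope="session")
def small_lognorm(small_truth):
    truth, markers = small_truth
    filtered, _ = qc_filter(truth)
    return select_hvg(normalize_log(filtered), n_top=5000), markers


@pytest.fixture
def tiny_counts():
    """Hand-sized 4-cell x 5-gene count matrix for exact checks."""
    values = np.array([
        [1.0, 1.0, 2.0, 0.0, 0.0],
        [2.0, 0.0, 1.0, 1.0, 0.0],
        [0.0, 3.0, 0.0, 2.0, 1.0],
        [1.0, 1.0, 1.0, 1.0, 1.0],
    ])
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(5)],
        cell_ids=[f"c{i}" for i in range(4)],
    )


@dataclass
class RepairExperiment:
    """Everything the end-to-end checks need, computed once."""

    lognorm: ExpressionMatrix
    marker_genes: list[str]
    pair: object                 # DegradedPair
    split: object                # SplitAssignment
    model: object                # trained TransformerRepairer
    x_orig_test: ExpressionMatrix
    x_deg_test: ExpressionMatrix
    x_rep_test: ExpressionMatrix
    test_labels: list[str]
    x_rep_all: ExpressionMatrix  # model applied to every cell
    panel: object                # ProteinPanel over all cells
    history: object


@pytest.fixture(scope="session")
def repair_experiment(small_lognorm) -> RepairExperiment:
    """Train the reduced Transformer on the standard synthetic benchmark.

    Conditions: 2000 cells x 500 genes, 4 types; degradation alpha=0.5,
    p_d=0.3, sigma_n=0.2; reduced model (embed 64, 2 layers, 4 heads,
    token_size 25) trained for at most 30 epochs.
    """
    lognorm, markers = small_lognorm
    marker_genes = [g for g in markers["gene_id"] if g in lognorm.gene_ids]
    pairs6 = select_panel_genes(
        markers[markers["gene_id"].isin(marker_genes)], n_pairs=6)
    panel = generate_protein_panel(lognorm, pairs6, noise_sd=0.3, seed=43)
    pair = degrade(lognorm, DegradationParams(alpha=0.5, dropout_rate=0.3,
                                              noise_sd=0.2, seed=7))
    split = split_dataset(lognorm.n_cells, labels=lognorm.cell_labels, seed=3)
    cfg = RepairModelConfig(n_genes=lognorm.n_genes, embed_dim=64,
                            num_layers=2, num_heads=4, ffn_dim=512,
                            token_size=25, dropout=0.0, seed=5)
    model = build_model(cfg)
    model, history = train(
        model, pair, split,
        TrainConfig(max_epochs=30, learning_rate=3e-3, seed=11))

    test = split.test_idx
    x_orig_test = pair.x_orig.subset_cells(test)
    x_deg_test = pair.x_deg.subset_cells(test)
    x_rep_test = x_deg_test.with_values(model.repair(x_deg_test.values))
    x_rep_all = pair.x_deg.with_values(model.repair(pair.x_deg.values))
    return RepairExperiment(
        lognorm=lognorm,
        marker_genes=marker_genes,
        pair=pair,
        split=split,
        model=model,
        x_orig_test=x_orig_test,
        x_deg_test=x_deg_test,
        x_rep_test=x_rep_test,
        test_labels=[lognorm.cell_labels[i] for i in test],
        x_rep_all=x_rep_all,
        panel=panel,
        history=history,
    )
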