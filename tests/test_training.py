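"""Splitting, the plateau scheduler and the training loop."""

import numpy as np
import pytest

from rnarepair import (
    DegradationParams,
    ExpressionMatrix,
    PlateauScheduler,
    RepairModelConfig,
    TrainConfig,
    build_model,
    degrade,
    grid_runner,
    split_dataset,
    train,
)
from rnarepair.errors import ValidationError


class TestSplitDataset:
    def test_exact_division_100_cells(self):
        s = split_dataset(100, seed=0)
        assert (len(s.train_idx), len(s.val_idx), len(s.test_idx)) == (80, 10, 10)

    @pytest.mark.parametrize("n", [37, 100, 401, 1009])
    def test_disjoint_cover(self, n):
        s = split_dataset(n, seed=1)
        all_idx = np.concatenate([s.train_idx, s.val_idx, s.test_idx])
        assert len(all_idx) == n
        assert len(set(all_idx)) == n

    def test_stratification_within_one_cell(self):
        labels = [f"t{i % 4}" for i in range(400)]
        s = split_dataset(400, labels=labels, seed=2)
        for part, frac in ((s.train_idx, 0.8), (s.val_idx, 0.1),
                           (s.test_idx, 0.1)):
            part_labels = [labels[i] for i in part]
            for t in ("t0", "t1", "t2", "t3"):
                expected = frac * 100
                assert abs(part_labels.count(t) - expected) <= 1

    def test_small_stratum_rejected(self):
        labels = ["a"] * 50 + ["b"] * 2
        with pytest.raises(ValidationError, match="stratum"):
            split_dataset(52, labels=labels, seed=3)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValidationError):
            split_dataset(10, fractions=(0.5, 0.5, 0.5))

    def test_deterministic_given_seed(self):
        a = split_dataset(123, seed=7)
        b = split_dataset(123, seed=7)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)


class TestPlateauScheduler:
    def test_halves_exactly_after_patience_flat_epochs(self):
        sched = PlateauScheduler(lr=1.0, patience=10, factor=0.5)
        lrs = [sched.step(1.0) for _ in range(11)]
        # epoch 0 establishes the best; epochs 1..9 wait; epoch 10 triggers
        assert lrs[:10] == [1.0] * 10
        assert lrs[10] == 0.5

    def test_improvement_resets_the_wait(self):
        sched = PlateauScheduler(lr=1.0, patience=3, factor=0.5)
        trace = [5.0, 5.0, 5.0, 4.0, 4.0, 4.0, 4.0]
        lrs = [sched.step(v) for v in trace]
        assert lrs == [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.5]

    def test_sub_threshold_improvement_counts_as_plateau(self):
        sched = PlateauScheduler(lr=1.0, patience=2, factor=0.5,
                                 rel_threshold=1e-3)
        lrs = [sched.step(v) for v in (1.0, 1.0 - 1e-6, 1.0 - 2e-6)]
        assert lrs[-1] == 0.5

    def test_replay_reproduces_recorded_lr_trace(self, repair_experiment):
        """The recorded lr sequence equals the schedule replayed on the
        recorded validation losses."""
        hist = repair_experiment.history
        sched = PlateauScheduler(lr=hist.learning_rate[0], patience=10,
                                 factor=0.5)
        lr = hist.learning_rate[0]
        for recorded_lr, val in zip(hist.learning_rate, hist.val_loss):
            assert recorded_lr == pytest.approx(lr)
            lr = sched.step(val)
        assert all(x >= y for x, y in zip(hist.learning_rate,
                                          hist.learning_rate[1:]))


def _identity_pair(n_cells=60, n_genes=10, seed=0):
    rng = np.random.default_rng(seed)
    m = ExpressionMatrix(
        values=rng.random((n_cells, n_genes)) * 2,
        gene_ids=[f"g{j}" for j in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(n_cells)],
        scale_tag="cp10k_log1p",
    )
    return degrade(m, DegradationParams(0.0, 0.0, 0.0, seed=0))


class TestTrainLoop:
    def test_learns_the_identity_task(self):
        pair = _identity_pair()
        split = split_dataset(60, seed=1)
        cfg = RepairModelConfig(n_genes=10, embed_dim=8, num_heads=2,
                                num_layers=1, ffn_dim=16, dropout=0.0,
                                token_size=5, seed=2)
        model = build_model(cfg)
        untrained = float(model.loss(pair.x_deg.values[split.val_idx],
                                     pair.x_orig.values[split.val_idx],
                                     training=False).data)
        model, hist = train(model, pair, split,
                            TrainConfig(batch_size=16, learning_rate=3e-3,
                                        max_epochs=60, seed=3))
        assert hist.best_val_loss < 0.25 * untrained

    def test_empty_train_split_rejected(self):
        pair = _identity_pair()
        from rnarepair.training import SplitAssignment
        split = SplitAssignment(train_idx=np.array([], dtype=int),
                                val_idx=np.arange(5),
                                test_idx=np.arange(5, 10))
        with pytest.raises(ValidationError):
            train(build_model(RepairModelConfig(
                n_genes=10, embed_dim=8, num_heads=2, num_layers=1,
                token_size=5, seed=0)), pair, split, TrainConfig())

    def test_history_is_deterministic_given_seeds(self):
        pair = _identity_pair(seed=4)
        split = split_dataset(60, seed=5)
        cfg = RepairModelConfig(n_genes=10, embed_dim=8, num_heads=2,
                                num_layers=1, ffn_dim=16, dropout=0.1,
                                token_size=5, seed=6)
        tcfg = TrainConfig(batch_size=16, max_epochs=5, seed=7)
        _, h1 = train(build_model(cfg), pair, split, tcfg)
        _, h2 = train(build_model(cfg), pair, split, tcfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_test_set_firewall(self, repair_experiment):
        """No held-out test cell enters a gradient step or the scheduler."""
        hist = repair_experiment.history
        test = set(map(int, repair_experiment.split.test_idx))
        assert not (hist.gradient_indices_seen & test)
        assert not (hist.scheduler_indices_seen & test)
        train_set = set(map(int, repair_experiment.split.train_idx))
        assert hist.gradient_indices_seen == train_set


class TestGridRunner:
    @pytest.fixture(scope="class")
    def small_setup(self):
        pair = _identity_pair(n_cells=50, n_genes=8, seed=8)
        split = split_dataset(50, seed=9)
        return pair, split

    def _cfg(self, **kw):
        base = dict(n_genes=8, embed_dim=8, num_heads=2, num_layers=1,
                    ffn_dim=16, dropout=0.0, token_size=4, seed=10)
        base.update(kw)
        return RepairModelConfig(**base)

    def test_singleton_grid_matches_direct_run(self, small_setup):
        pair, split = small_setup
        tcfg = TrainConfig(batch_size=16, max_epochs=3, seed=11)
        table = grid_runner(pair, split, [self._cfg()], tcfg)
        model, _ = train(build_model(self._cfg()), pair, split, tcfg)
        from rnarepair import technical_metrics
        direct = technical_metrics(
            model.repair(pair.x_deg.values[split.test_idx]),
            pair.x_orig.values[split.test_idx])
        assert len(table) == 1
        assert table.loc[0, "status"] == "ok"
        assert table.loc[0, "test_mse"] == pytest.approx(direct.mse)

    def test_duplicate_configs_give_identical_rows(self, small_setup):
        pair, split = small_setup
        tcfg = TrainConfig(batch_size=16, max_epochs=2, seed=12)
        table = grid_runner(pair, split, [self._cfg(), self._cfg()], tcfg)
        assert table.loc[0, "test_mse"] == table.loc[1, "test_mse"]

    def test_two_by_two_smoke_matrix(self, small_setup):
        pair, split = small_setup
        grid = [self._cfg(embed_dim=e, num_layers=l)
                for e in (8, 16) for l in (1, 2)]
        table = grid_runner(pair, split, grid,
                            TrainConfig(batch_size=16, max_epochs=2, seed=13))
        assert len(table) == 4
        assert (table["status"] == "ok").all()
        assert np.isfinite(table["test_mse"]).all()
        assert np.isfinite(table["test_pearson"]).all()

    def test_failing_run_recorded_not_raised(self, small_setup):
        pair, split = small_setup
        bad = self._cfg(n_genes=12)  # mismatched with the 8-gene data
        table = grid_runner(pair, split, [bad, self._cfg()],
                            TrainConfig(batch_size=16, max_epochs=2, seed=14))
        assert table.loc[0, "status"] == "failed"
        assert table.loc[1, "status"] == "ok"

    def test_empty_grid_rejected(self, small_setup):
        pair, split = small_setup
        with pytest.raises(ValidationError):
            grid_runner(pair, split, [], TrainConfig())
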