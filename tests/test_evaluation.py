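"""Technical and biological metric implementations against independent oracles."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rnarepair import (
    ExpressionMatrix,
    cell_type_separation,
    classifier_validation,
    deg_preservation,
    marker_recovery,
    orthogonal_protein_validation,
    overall_biological,
    paired_significance,
    technical_metrics,
)
from rnarepair.errors import LookupError_, ValidationError
from rnarepair.evaluation import rank_genes_one_vs_rest
from rnarepair.synthetic import ProteinPanel


def brute_force_average_precision(y_true, scores):
    """Independent PR-AUC oracle: average precision by threshold enumeration.

    AP = sum over positives, in decreasing-score order, of precision at each
    positive's threshold, divided by the number of positives. Ties share the
    precision of their common threshold.
    """
    order = np.argsort(-scores, kind="stable")
    y = np.asarray(y_true)[order]
    s = np.asarray(scores)[order]
    n_pos = y.sum()
    ap = 0.0
    tp = fp = 0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:  # threshold block (ties)
            j += 1
        tp_block = int(y[i:j].sum())
        fp_block = (j - i) - tp_block
        tp += tp_block
        fp += fp_block
        if tp_block:
            ap += tp_block * tp / (tp + fp)
        i = j
    return ap / n_pos


def brute_force_rank_sum_top_k(values, labels, group, k):
    """Independent DEG oracle: normal-approximation rank-sum per gene."""
    labels = np.asarray(labels)
    mask = labels == group
    n1, n2 = mask.sum(), (~mask).sum()
    stats_out = []
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j])
        w = ranks[mask].sum()
        mu = n1 * (n1 + n2 + 1) / 2.0
        sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        z = (w - mu) / sigma if sigma > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        lfc = abs(values[mask, j].mean() - values[~mask, j].mean())
        stats_out.append((p, -lfc, j))
    stats_out.sort()
    return {j for _, _, j in stats_out[:k]}


class TestTechnicalMetrics:
    def test_identity_is_perfect(self):
        x = np.random.default_rng(0).random((10, 8))
        m = technical_metrics(x, x)
        assert m.mse == 0.0
        assert m.pearson == pytest.approx(1.0)

    def test_negated_zero_mean_input_has_pearson_minus_one(self):
        x = np.random.default_rng(1).normal(size=(20, 5))
        x -= x.mean()
        m = technical_metrics(-x, x)
        assert m.pearson == pytest.approx(-1.0)

    def test_constant_input_warns_and_returns_nan(self):
        x = np.ones((4, 4))
        with pytest.warns(UserWarning, match="constant"):
            m = technical_metrics(x, x)
        assert np.isnan(m.pearson)

    def test_pr_auc_matches_enumeration_on_worked_example(self):
        orig = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 0.0])  # positives at 1, 3
        scores = np.array([0.9, 0.8, 0.7, 0.1, 0.05, 0.01])
        m = technical_metrics(scores.reshape(1, -1), orig.reshape(1, -1))
        assert m.pr_auc == pytest.approx(
            brute_force_average_precision(orig > 0, scores))

    def test_pr_auc_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(5, 1000))
            y = (rng.random(n) < 0.3).astype(float)
            if y.min() == y.max():
                continue
            scores = rng.normal(size=n) + y
            m = technical_metrics(scores.reshape(1, -1), y.reshape(1, -1))
            assert m.pr_auc == pytest.approx(
                brute_force_average_precision(y > 0, scores), abs=1e-12)

    def test_f1_threshold_behaviour(self):
        orig = np.array([[0.0, 2.0, 2.0, 0.0]])
        hat = np.array([[0.05, 1.5, 0.02, 0.3]])  # one FN, one FP at tau=0.1
        m = technical_metrics(hat, orig)
        assert m.f1 == pytest.approx(2 * 1 / (2 * 1 + 1 + 1))


class TestCellTypeSeparation:
    def test_two_distant_clusters_score_near_100(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.01, size=(20, 10))
        b = rng.normal(50, 0.01, size=(20, 10))
        x = np.vstack([a, b])
        labels = ["a"] * 20 + ["b"] * 20
        assert cell_type_separation(x, labels) > 99.0

    def test_shuffled_labels_score_lower(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(0, 1, (30, 5)), rng.normal(6, 1, (30, 5))])
        labels = np.array(["a"] * 30 + ["b"] * 30)
        good = cell_type_separation(x, labels)
        shuffled = labels.copy()
        rng.shuffle(shuffled)
        assert cell_type_separation(x, shuffled) < good

    def test_affine_map_is_applied(self):
        # orthogonal two-cluster geometry with known silhouette sign
        x = np.array([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0]])
        labels = ["a", "a", "b", "b"]
        score = cell_type_separation(x, labels, n_pcs=2)
        # silhouette ~ (10 - 0.1) / 10 -> score well above 95
        assert 95.0 < score <= 100.0

    def test_single_label_rejected(self):
        with pytest.raises(ValidationError):
            cell_type_separation(np.zeros((4, 3)), ["a"] * 4)


class TestDEGPreservation:
    def test_identical_matrices_score_100(self):
        rng = np.random.default_rng(5)
        x = rng.random((40, 25))
        labels = ["a"] * 20 + ["b"] * 20
        res = deg_preservation(x, x, labels, top_k=5)
        assert res.jaccard == 1.0 and res.f1 == 1.0 and res.score == 100.0

    def test_top_sets_match_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        n_cells, n_genes, k = 30, 20, 5
        labels = np.array(["a"] * 15 + ["b"] * 15)
        x = rng.normal(size=(n_cells, n_genes))
        x[labels == "a", :5] += 2.0  # planted DEGs
        for group in ("a", "b"):
            ours = set(rank_genes_one_vs_rest(x, labels, group, k))
            oracle = brute_force_rank_sum_top_k(x, labels, group, k)
            assert ours == oracle

    def test_column_permutation_scores_near_chance(self):
        rng = np.random.default_rng(7)
        n_genes, k = 400, 20
        labels = ["a"] * 60 + ["b"] * 60
        x = rng.normal(size=(120, n_genes))
        x[:60, :30] += 1.5
        perm = rng.permutation(n_genes)
        res = deg_preservation(x[:, perm], x, labels, top_k=k)
        # chance overlap scale ~ k/n_genes; generous ceiling
        assert res.score < 25.0

    def test_top_k_bound_enforced(self):
        with pytest.raises(ValidationError):
            deg_preservation(np.zeros((4, 3)), np.zeros((4, 3)),
                             ["a", "a", "b", "b"], top_k=10)


class TestMarkerRecovery:
    def _ids(self, n):
        return [f"g{j}" for j in range(n)]

    def test_identity_scores_100(self):
        x = np.random.default_rng(8).random((15, 6))
        assert marker_recovery(x, x, self._ids(6), ["g1", "g4"]) == 100.0

    def test_rank_reversal_clips_to_zero(self):
        x = np.random.default_rng(9).random((15, 4))
        assert marker_recovery(-x, x, self._ids(4), ["g0", "g3"]) == 0.0

    def test_hand_computed_spearman(self):
        # ranks: hat [1,2,3,4] vs orig [1,2,4,3]: rho = 1 - 6*2/(4*15) = 0.8
        hat = np.array([[1.0], [2.0], [3.0], [4.0]])
        orig = np.array([[10.0], [20.0], [40.0], [30.0]])
        assert marker_recovery(hat, orig, ["g0"], ["g0"]) == pytest.approx(80.0)

    def test_missing_marker_listed_in_error(self):
        x = np.zeros((4, 2))
        with pytest.raises(LookupError_, match="NOPE"):
            marker_recovery(x, x, self._ids(2), ["g0", "NOPE"])


class TestScoreRanges:
    """Every score stays in its documented range for arbitrary valid input."""

    @given(seed=st.integers(0, 10_000), n_cells=st.integers(8, 30),
           n_genes=st.integers(4, 15))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scores_respect_bounds(self, seed, n_cells, n_genes):
        rng = np.random.default_rng(seed)
        # sparse truth so the expressed/unexpressed task has both classes
        x_orig = rng.random((n_cells, n_genes)) * 3
        x_orig *= rng.random(x_orig.shape) < 0.7
        x_hat = np.maximum(x_orig + rng.normal(0, 1, x_orig.shape), 0)
        labels = ["a"] * (n_cells // 2) + ["b"] * (n_cells - n_cells // 2)
        ids = [f"g{j}" for j in range(n_genes)]

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = technical_metrics(x_hat, x_orig)
        assert np.isnan(m.pearson) or -1 <= m.pearson <= 1
        assert np.isnan(m.pr_auc) or 0 <= m.pr_auc <= 1
        assert np.isnan(m.f1) or 0 <= m.f1 <= 1
        assert m.mse >= 0
        assert 0 <= cell_type_separation(x_hat, labels) <= 100
        res = deg_preservation(x_hat, x_orig, labels, top_k=3)
        assert 0 <= res.jaccard <= 1 and 0 <= res.f1 <= 1
        assert 0 <= res.score <= 100
        assert 0 <= marker_recovery(x_hat, x_orig, ids, ids[:2]) <= 100


class TestOverallBiological:
    @pytest.mark.parametrize("triple,expected", [
        ((65.210, 57.410, 66.450), 63.023),
        ((68.530, 42.760, 65.250), 58.847),
        ((51.750, 52.910, 59.100), 54.587),
        ((66.500, 43.650, 65.510), 58.553),
        ((54.230, 64.950, 69.010), 62.730),
        ((0.0, 0.0, 0.0), 0.0),
    ])
    def test_arithmetic_mean_identities(self, triple, expected):
        assert overall_biological(*triple) == pytest.approx(expected, abs=5e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            overall_biological(101.0, 50.0, 50.0)


class TestPairedSignificance:
    def test_identical_samples_are_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        res = paired_significance(a, a)
        assert res.degenerate
        assert res.p_value == 1.0 and res.cohen_d == 0.0

    def test_hand_computed_effect_size(self):
        b = np.array([0.0, 0.0, 0.0])
        a = np.array([1.0, 2.0, 3.0])
        res = paired_significance(a, b)
        assert res.mean_diff == pytest.approx(2.0)
        assert res.cohen_d == pytest.approx(2.0)
        # t = d * sqrt(n) = 2 * sqrt(3)
        t = stats.ttest_rel(a, b).statistic
        assert t == pytest.approx(2 * np.sqrt(3))

    def test_sign_convention(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 50)
        res = paired_significance(a, a + 1.0 + rng.normal(0, 0.2, 50))
        assert res.mean_diff < 0 and res.cohen_d < 0

    def test_type_i_error_near_nominal(self):
        """Null rejection rate at alpha=0.05 stays within Monte-Carlo error."""
        rng = np.random.default_rng(11)
        n_reps, n = 2000, 100
        rejections = 0
        for _ in range(n_reps):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            if paired_significance(a, b).p_value < 0.05:
                rejections += 1
        rate = rejections / n_reps
        assert rate == pytest.approx(0.05, abs=0.015)


class TestOrthogonalValidation:
    def _setup(self, seed=12):
        rng = np.random.default_rng(seed)
        n = 100
        genes = ["g0", "g1", "g2"]
        orig = ExpressionMatrix(rng.random((n, 3)) * 3, genes,
                                [f"c{i}" for i in range(n)],
                                scale_tag="cp10k_log1p")
        deg = orig.with_values(orig.values * (rng.random((n, 3)) > 0.4))
        panel = ProteinPanel(
            protein_values=orig.values + rng.normal(0, 0.1, (n, 3)),
            protein_names=["P0", "P1", "P2"],
            pairs=[("P0", "g0"), ("P1", "g1"), ("P2", "g2")],
        )
        return orig, deg, panel

    def test_full_recovery_limit(self):
        orig, deg, panel = self._setup()
        res = orthogonal_protein_validation(orig, deg, orig.copy(), panel)
        assert res.recovery_fraction == pytest.approx(1.0)

    def test_no_recovery_limit(self):
        orig, deg, panel = self._setup()
        res = orthogonal_protein_validation(orig, deg, deg.copy(), panel)
        assert res.recovery_fraction == pytest.approx(0.0)

    def test_undefined_recovery_flagged(self):
        orig, _, panel = self._setup()
        with pytest.warns(UserWarning, match="undefined"):
            res = orthogonal_protein_validation(orig, orig.copy(),
                                                orig.copy(), panel)
        assert not res.recovery_defined
        assert np.isnan(res.recovery_fraction)


class TestClassifierValidation:
    def test_returns_one_accuracy_per_fold(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(60, 4))
        labels = ["a", "b"] * 30
        accs, mean = classifier_validation(x, labels, folds=5, seed=0)
        assert len(accs) == 5
        assert mean == pytest.approx(accs.mean())

    def test_separable_clusters_classify_perfectly(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 0.3, size=(40, 5))
        b = rng.normal(8, 0.3, size=(40, 5))
        x = np.vstack([a, b])
        labels = ["a"] * 40 + ["b"] * 40
        _, mean = classifier_validation(x, labels, folds=5, seed=1)
        assert mean >= 0.99

    def test_shuffled_labels_classify_at_chance(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=(400, 6))
        labels = [f"t{i % 4}" for i in range(400)]
        _, mean = classifier_validation(x, labels, folds=5, seed=2)
        assert mean == pytest.approx(0.25, abs=0.08)

    def test_class_smaller_than_folds_rejected(self):
        x = np.zeros((7, 2))
        labels = ["a"] * 4 + ["b"] * 3
        with pytest.raises(ValidationError):
            classifier_validation(x, labels, folds=5, seed=0)
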