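"""Technical and biological fidelity metrics for repaired expression data.

Technical metrics (MSE, Pearson, PR-AUC, F1) measure numerical agreement with
the original profile, treating "was this gene expressed?" as the binary task
behind PR-AUC/F1. Biological metrics measure whether the repaired data still
supports downstream analysis: cell-type separation (silhouette in PCA space),
preservation of top differentially expressed genes (Jaccard/F1 of one-vs-rest
rank-sum top-k sets), and marker-gene recovery (Spearman correlation per
curated marker). The overall biological score is the arithmetic mean of the
three, on a 0-100 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, f1_score, silhouette_score
from sklearn.model_selection import StratifiedKFold

from .errors import LookupError_, ShapeError, ValidationError
from .matrix import ExpressionMatrix
from .synthetic import ProteinPanel

DEFAULT_F1_THRESHOLD = 0.1
DEFAULT_TOP_K = 50
DEFAULT_N_PCS = 50


# ---------------------------------------------------------------------------
# technical metrics


@dataclass(frozen=True)
class TechnicalMetrics:
    mse: float
    pearson: float
    pr_auc: float
    f1: float


def technical_metrics(
    x_hat: np.ndarray,
    x_orig: np.ndarray,
    f1_threshold: float = DEFAULT_F1_THRESHOLD,
) -> TechnicalMetrics:
    """MSE/Pearson over all entries; PR-AUC/F1 on expressed-vs-unexpressed.

    The positive class is "expressed in the original" (x_orig > 0); the
    predicted score is the repaired value, binarized at ``f1_threshold`` for
    F1. Degenerate inputs (constant arrays, single-class truth) yield NaN with
    a warning rather than a silently misleading 0.
    """
    x_hat = np.asarray(x_hat, dtype=np.float64)
    x_orig = np.asarray(x_orig, dtype=np.float64)
    if x_hat.shape != x_orig.shape:
        raise ShapeError(f"shape mismatch {x_hat.shape} vs {x_orig.shape}")

    a, b = x_hat.ravel(), x_orig.ravel()
    mse = float(np.mean((a - b) ** 2))

    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant input: Pearson correlation is undefined",
                      stacklevel=2)
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(a, b)[0, 1])

    y_true = (b > 0).astype(int)
    if y_true.min() == y_true.max():
        warnings.warn("single-class truth: PR-AUC/F1 undefined", stacklevel=2)
        pr_auc = f1 = float("nan")
    else:
        pr_auc = float(average_precision_score(y_true, a))
        f1 = float(f1_score(y_true, (a > f1_threshold).astype(int),
                            zero_division=0))
    return TechnicalMetrics(mse=mse, pearson=pearson, pr_auc=pr_auc, f1=f1)


# ---------------------------------------------------------------------------
# biological metrics


def cell_type_separation(
    x_hat: np.ndarray,
    labels: Sequence[str],
    n_pcs: int = DEFAULT_N_PCS,
) -> float:
    """Silhouette-based cluster-separation score on a 0-100 scale.

    The mean silhouette coefficient s (Euclidean distance on the top
    ``n_pcs`` principal components, or all components when fewer exist) is
    mapped affinely to [0, 100] via (s + 1) / 2 * 100.
    """
    x_hat = np.asarray(x_hat, dtype=np.float64)
    labels = np.asarray([str(x) for x in labels])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("silhouette needs >= 2 distinct labels")
    if counts.min() < 2:
        raise ValidationError("every label needs >= 2 cells")

    k = min(n_pcs, x_hat.shape[1], x_hat.shape[0] - 1)
    if k < x_hat.shape[1]:
        pcs = PCA(n_components=k, svd_solver="full").fit_transform(x_hat)
    else:
        pcs = x_hat
    s = float(silhouette_score(pcs, labels, metric="euclidean"))
    return (s + 1.0) / 2.0 * 100.0


def rank_genes_one_vs_rest(
    values: np.ndarray,
    labels: Sequence[str],
    group: str,
    top_k: int,
    gene_ids: Optional[Sequence[str]] = None,
) -> list[int]:
    """Top-k differential genes for ``group`` vs the rest (column indices).

    Per gene, a two-sided Wilcoxon rank-sum test compares the group's cells
    against all others; genes rank by ascending p-value, ties broken by larger
    absolute log-fold-change (difference of group means on the log scale),
    then by gene id.
    """
    labels = np.asarray([str(x) for x in labels])
    in_group = labels == str(group)
    x_in, x_out = values[in_group], values[~in_group]
    with np.errstate(invalid="ignore"):
        res = stats.ranksums(x_in, x_out, axis=0)
    pvals = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    abs_lfc = np.abs(x_in.mean(axis=0) - x_out.mean(axis=0))
    ids = (list(gene_ids) if gene_ids is not None
           else [f"{j}" for j in range(values.shape[1])])
    order = sorted(range(values.shape[1]),
                   key=lambda j: (pvals[j], -abs_lfc[j], ids[j]))
    return order[:top_k]


@dataclass(frozen=True)
class DEGPreservation:
    jaccard: float
    f1: float
    score: float  # mean(jaccard, f1) * 100
    per_label: dict[str, tuple[float, float]] = field(default_factory=dict)


def _set_overlap(a: set[int], b: set[int]) -> tuple[float, float]:
    inter = len(a & b)
    jac = inter / len(a | b) if (a | b) else 1.0
    f1 = 2 * inter / (len(a) + len(b)) if (a or b) else 1.0
    return jac, f1


def deg_preservation(
    x_hat: np.ndarray,
    x_orig: np.ndarray,
    labels: Sequence[str],
    top_k: int = DEFAULT_TOP_K,
    gene_ids: Optional[Sequence[str]] = None,
) -> DEGPreservation:
    """Overlap of top differential-gene sets before vs after repair.

    For every cell type, the top-k one-vs-rest rank-sum genes are computed
    from the original and from the repaired matrix; Jaccard and F1 of the two
    sets are averaged over cell types and summarized as mean(J, F1) * 100.
    """
    x_hat = np.asarray(x_hat, dtype=np.float64)
    x_orig = np.asarray(x_orig, dtype=np.float64)
    if x_hat.shape != x_orig.shape:
        raise ShapeError("matrices must share shape")
    if top_k > x_hat.shape[1]:
        raise ValidationError("top_k exceeds the number of genes")
    uniq = sorted(set(str(x) for x in labels))
    if len(uniq) < 2:
        raise ValidationError("DEG preservation needs >= 2 labels")

    per_label: dict[str, tuple[float, float]] = {}
    for lab in uniq:
        s_orig = set(rank_genes_one_vs_rest(x_orig, labels, lab, top_k,
                                            gene_ids))
        s_hat = set(rank_genes_one_vs_rest(x_hat, labels, lab, top_k,
                                           gene_ids))
        per_label[lab] = _set_overlap(s_orig, s_hat)

    jac = float(np.mean([v[0] for v in per_label.values()]))
    f1 = float(np.mean([v[1] for v in per_label.values()]))
    return DEGPreservation(jaccard=jac, f1=f1,
                           score=(jac + f1) / 2.0 * 100.0,
                           per_label=per_label)


def marker_recovery(
    x_hat: np.ndarray,
    x_orig: np.ndarray,
    gene_ids: Sequence[str],
    marker_genes: Sequence[str],
) -> float:
    """Mean Spearman correlation of marker-gene columns, clipped at 0, x100.

    A negative correlation counts as zero recovery, keeping the score in
    [0, 100].
    """
    gene_ids = [str(g) for g in gene_ids]
    missing = [g for g in marker_genes if g not in gene_ids]
    if missing:
        raise LookupError_(f"marker genes absent from matrix: {missing}")
    if not marker_genes:
        raise ValidationError("marker_genes must be nonempty")
    x_hat = np.asarray(x_hat, dtype=np.float64)
    x_orig = np.asarray(x_orig, dtype=np.float64)

    rhos = []
    for g in marker_genes:
        j = gene_ids.index(g)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = stats.spearmanr(x_hat[:, j], x_orig[:, j]).statistic
        rhos.append(max(float(rho), 0.0) if np.isfinite(rho) else 0.0)
    return float(np.mean(rhos)) * 100.0


def overall_biological(separation: float, deg: float, marker: float) -> float:
    """Arithmetic mean of the three biological scores, to 3 decimals."""
    for name, v in (("separation", separation), ("deg", deg),
                    ("marker", marker)):
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"{name} score {v} outside [0, 100]")
    return round((separation + deg + marker) / 3.0, 3)


@dataclass(frozen=True)
class MetricsReport:
    """Full technical + biological scorecard for one repaired matrix."""

    mse: float
    pearson: float
    pr_auc: float
    f1: float
    cell_type_separation: float
    deg_preservation: float
    marker_recovery: float
    overall_biological: float

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in (
            "mse", "pearson", "pr_auc", "f1", "cell_type_separation",
            "deg_preservation", "marker_recovery", "overall_biological")}


def compute_report(
    x_hat: ExpressionMatrix,
    x_orig: ExpressionMatrix,
    marker_genes: Sequence[str],
    top_k: int = DEFAULT_TOP_K,
    f1_threshold: float = DEFAULT_F1_THRESHOLD,
) -> MetricsReport:
    """Evaluate a repaired matrix against its original on every metric.

    Cell labels are taken from ``x_orig``.
    """
    if x_orig.cell_labels is None:
        raise ValidationError("x_orig must carry cell labels")
    tech = technical_metrics(x_hat.values, x_orig.values, f1_threshold)
    sep = cell_type_separation(x_hat.values, x_orig.cell_labels)
    deg = deg_preservation(x_hat.values, x_orig.values, x_orig.cell_labels,
                           top_k=top_k, gene_ids=x_orig.gene_ids)
    mark = marker_recovery(x_hat.values, x_orig.values, x_orig.gene_ids,
                           marker_genes)
    return MetricsReport(
        mse=tech.mse, pearson=tech.pearson, pr_auc=tech.pr_auc, f1=tech.f1,
        cell_type_separation=sep, deg_preservation=deg.score,
        marker_recovery=mark,
        overall_biological=overall_biological(sep, deg.score, mark),
    )


# ---------------------------------------------------------------------------
# significance testing


@dataclass(frozen=True)
class PairedTestResult:
    p_value: float
    cohen_d: float
    n: int
    mean_diff: float
    degenerate: bool = False


def paired_significance(metric_a: Sequence[float],
                        metric_b: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test with the paired-samples Cohen's d.

    d = mean(a - b) / SD(a - b) with the n-1 denominator. Identical samples
    are reported as degenerate (p = 1, d = 0) rather than raising.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError("paired samples must be equal-length vectors")
    n = len(a)
    if n < 2:
        raise ValidationError("need at least 2 pairs")
    diff = a - b
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        return PairedTestResult(p_value=1.0, cohen_d=0.0, n=n,
                                mean_diff=mean_diff, degenerate=True)
    t = stats.ttest_rel(a, b)
    return PairedTestResult(p_value=float(t.pvalue),
                            cohen_d=mean_diff / sd, n=n,
                            mean_diff=mean_diff)


# ---------------------------------------------------------------------------
# orthogonal protein validation


@dataclass(frozen=True)
class OrthogonalValidationResult:
    """RNA-protein concordance under original/degraded/repaired conditions."""

    per_pair: pd.DataFrame            # columns: protein, gene, orig, deg, rep
    mean_orig: float
    sd_orig: float
    mean_deg: float
    sd_deg: float
    mean_rep: float
    sd_rep: float
    recovery_fraction: float          # NaN when undefined
    recovery_defined: bool
    paired_test: PairedTestResult     # repaired vs degraded correlations


def orthogonal_protein_validation(
    rna_orig: ExpressionMatrix,
    rna_deg: ExpressionMatrix,
    rna_rep: ExpressionMatrix,
    panel: ProteinPanel,
) -> OrthogonalValidationResult:
    """Spearman(RNA, protein) per pair and condition, plus signal recovery.

    The protein readout is independent of the RNA degradation, so the drop of
    correlation under degradation and its return after repair measure how much
    real biological signal the repair restores. recovery_fraction linearly
    interpolates the repaired mean between the degraded (0) and original (1)
    means.
    """
    rows = []
    for col, (protein, gene) in enumerate(panel.pairs):
        prot = panel.protein_values[:, col]
        row = {"protein": protein, "gene": gene}
        for name, m in (("orig", rna_orig), ("deg", rna_deg),
                        ("rep", rna_rep)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = stats.spearmanr(prot, m.gene_column(gene)).statistic
            row[name] = float(rho) if np.isfinite(rho) else 0.0
        rows.append(row)
    per_pair = pd.DataFrame(rows, columns=["protein", "gene", "orig", "deg",
                                           "rep"])
    if per_pair.empty:
        raise ValidationError("protein panel has no pairs")

    mean_orig, mean_deg, mean_rep = (float(per_pair[c].mean())
                                     for c in ("orig", "deg", "rep"))
    sd_orig, sd_deg, sd_rep = (
        float(per_pair[c].std(ddof=1)) if len(per_pair) > 1 else 0.0
        for c in ("orig", "deg", "rep"))

    lost = mean_orig - mean_deg
    if lost == 0.0:
        recovery, defined = float("nan"), False
        warnings.warn("degradation did not change the mean correlation; "
                      "recovery fraction undefined", stacklevel=2)
    else:
        recovery, defined = (mean_rep - mean_deg) / lost, True

    test = paired_significance(per_pair["rep"], per_pair["deg"])
    return OrthogonalValidationResult(
        per_pair=per_pair,
        mean_orig=mean_orig, sd_orig=sd_orig,
        mean_deg=mean_deg, sd_deg=sd_deg,
        mean_rep=mean_rep, sd_rep=sd_rep,
        recovery_fraction=recovery, recovery_defined=defined,
        paired_test=test,
    )


# ---------------------------------------------------------------------------
# downstream classifier check


def classifier_validation(
    x: np.ndarray,
    labels: Sequence[str],
    folds: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Stratified k-fold logistic-regression cell-type classification.

    Returns the per-fold accuracies and their mean; a data representation
    that preserves cell identity should classify well.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray([str(v) for v in labels])
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValidationError(
            f"smallest class has {counts.min()} cells; need >= {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(x, y):
        clf = LogisticRegression(max_iter=2000, random_state=seed)
        clf.fit(x[tr], y[tr])
        accs.append(float(clf.score(x[te], y[te])))
    accs = np.array(accs)
    return accs, float(accs.mean())
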