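"""Confusion metrics, ROC/AUC, and cross-validation engines.

Cross-validated metrics are POOLED: every fold's held-out predictions and
decision scores are collected into one vector and a single metric report is
computed over the union.  This keeps jackknife (leave-one-out) and K-fold on
one code path and leaves MCC well-defined even when individual folds are
tiny or single-class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .sequence_io import LabeledDataset

if TYPE_CHECKING:  # pragma: no cover
    from .pseudo_components import PropertyIndex, PseParams
    from .svm_model import SvmParams


class EvaluationError(ValueError):
    pass


JACKKNIFE = "jackknife"


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class RocCurve:
    """Tie-aware ROC: (FPR, TPR) points from (0,0) to (1,1) plus AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class MetricReport:
    counts: ConfusionCounts
    acc: float
    sn: float
    sp: float
    mcc: float
    roc: RocCurve | None = None

    @property
    def auc(self) -> float:
        if self.roc is None:
            raise EvaluationError("no ROC attached to this report")
        return self.roc.auc

    def scores(self) -> dict[str, float]:
        out = {"acc": self.acc, "mcc": self.mcc, "sn": self.sn, "sp": self.sp}
        out["auc"] = self.roc.auc if self.roc is not None else float("nan")
        return out


def compute_metrics(true: np.ndarray, pred: np.ndarray) -> MetricReport:
    """Confusion counts plus Acc, Sn, Sp and the Matthews correlation.

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); when any
    factor of the denominator is zero MCC is defined as 0.  Sn (Sp) is 0
    when no positives (negatives) were evaluated.
    """
    true = np.asarray(true, int)
    pred = np.asarray(pred, int)
    if true.shape != pred.shape:
        raise EvaluationError(
            f"length mismatch: {true.shape} truth vs {pred.shape} predictions"
        )
    if true.size == 0:
        raise EvaluationError("empty evaluation")
    tp = int(np.sum((true == 1) & (pred == 1)))
    fp = int(np.sum((true == -1) & (pred == 1)))
    tn = int(np.sum((true == -1) & (pred == -1)))
    fn = int(np.sum((true == 1) & (pred == -1)))
    counts = ConfusionCounts(tp, fp, tn, fn)
    acc = (tp + tn) / counts.total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricReport(counts, acc, sn, sp, mcc)


def roc_auc(true: np.ndarray, scores: np.ndarray) -> RocCurve:
    """ROC points at every distinct threshold and the rank-statistic AUC.

    The AUC equals the Mann–Whitney statistic with ties counted 1/2, i.e.
    the trapezoidal area under the tie-aware curve.
    """
    true = np.asarray(true, int)
    scores = np.asarray(scores, float)
    if true.shape != scores.shape:
        raise EvaluationError("length mismatch between truth and scores")
    if len(set(true.tolist())) < 2:
        raise EvaluationError("AUC undefined: only one class in truth")
    fpr, tpr, thr = roc_curve(true, scores, pos_label=1, drop_intermediate=False)
    auc = float(roc_auc_score(true, scores))
    return RocCurve(thr, fpr, tpr, auc)


def write_roc_points(path, roc: RocCurve) -> None:
    """TSV of (threshold, FPR, TPR); the first threshold is +inf by convention."""
    with open(path, "w") as fh:
        fh.write("threshold\tFPR\tTPR\n")
        for t, f, s in zip(roc.thresholds, roc.fpr, roc.tpr):
            fh.write(f"{float(t)!r}\t{float(f)!r}\t{float(s)!r}\n")


def plot_roc(path, roc: RocCurve, title: str = "ROC") -> None:
    """Render the ROC curve to a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(roc.fpr, roc.tpr, lw=1.5, label=f"AUC = {roc.auc:.4f}")
    ax.plot([0, 1], [0, 1], ls="--", lw=0.8, color="grey")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """Fold id per sample; K folds (jackknife = one sample per fold)."""

    k: int
    fold_of: np.ndarray  # shape (N,), values in 0..k-1
    seed: int
    jackknife: bool = False

    @property
    def n_samples(self) -> int:
        return len(self.fold_of)

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.fold_of == fold)
        train = np.flatnonzero(self.fold_of != fold)
        return train, test


def make_folds(labels: np.ndarray, k: int | str, seed: int) -> FoldAssignment:
    """Stratified, seeded K-fold assignment, or jackknife (one per fold).

    Stratification assigns each class's shuffled members round-robin to
    folds, so per-fold class counts differ from proportionality by at most
    one.  Jackknife folds follow dataset order.
    """
    labels = np.asarray(labels, int)
    n = len(labels)
    if k == JACKKNIFE:
        return FoldAssignment(n, np.arange(n), seed, jackknife=True)
    k = int(k)
    if k < 2 or k > n:
        raise EvaluationError(f"K must satisfy 2 <= K <= {n}, got {k}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    # Round-robin within each class, continuing one global fold counter
    # across classes: per-fold class counts stay within one of
    # proportionality, total fold sizes within one of n/K, and K = N
    # degenerates to exactly one sample per fold (leave-one-out).
    start = 0
    for cls in (1, -1):
        members = np.flatnonzero(labels == cls)
        perm = rng.permutation(members)
        fold_of[perm] = (start + np.arange(len(perm))) % k
        start = (start + len(perm)) % k
    return FoldAssignment(k, fold_of, seed)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def pooled_cv_from_matrix(
    matrix: np.ndarray,
    labels: np.ndarray,
    svm_params: "SvmParams",
    folds: FoldAssignment,
) -> MetricReport:
    """Pooled cross-validation over a precomputed feature matrix.

    This is the single scoring path shared by :func:`cross_validate` and the
    parameter-grid search, so both agree by construction.
    """
    from .svm_model import train_svm

    if folds.n_samples != len(labels):
        raise EvaluationError("fold assignment does not match dataset size")
    pooled_scores = np.empty(len(labels))
    pooled_pred = np.empty(len(labels), dtype=int)
    for fold in range(folds.k):
        train_idx, test_idx = folds.split(fold)
        if len(test_idx) == 0:
            continue
        train_labels = labels[train_idx]
        if len(set(train_labels.tolist())) < 2:
            raise EvaluationError(
                f"training split of fold {fold} contains a single class"
            )
        state = train_svm(matrix[train_idx], train_labels, svm_params)
        s = state.decision_scores(matrix[test_idx])
        pooled_scores[test_idx] = s
        pooled_pred[test_idx] = np.where(s >= 0, 1, -1)
    report = compute_metrics(labels, pooled_pred)
    roc = roc_auc(labels, pooled_scores)
    return MetricReport(report.counts, report.acc, report.sn, report.sp,
                        report.mcc, roc)


def cross_validate(
    dataset: LabeledDataset,
    pse_params: "PseParams",
    svm_params: "SvmParams",
    folds: FoldAssignment,
    index: "PropertyIndex",
) -> MetricReport:
    """Train on each fold's complement, score its held-out samples, and pool.

    Returns one :class:`MetricReport` (with ROC) over the pooled held-out
    predictions, independent of the order folds are evaluated in.
    """
    from .pseudo_components import extract_features

    matrix, labels = extract_features(dataset, pse_params, index)
    return pooled_cv_from_matrix(matrix, labels, svm_params, folds)
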