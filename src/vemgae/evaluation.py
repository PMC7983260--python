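"""Cross-validation over known associations and imbalanced-data metrics.

Folds partition the known positives only; unknown pairs stay 0.  For each
fold the model trains on the masked matrix and is scored on the held-out
positives (label 1) against every pair that is 0 in the full matrix
(label 0); training positives are excluded from evaluation.

Because the negatives vastly outnumber the positives, the report includes
the precision-recall area, metrics at fixed high specificity (0.95, 0.99)
and true-positive counts among the top-k ranked pairs, alongside AUROC.
AUROC uses the tie-aware rank-sum (Mann-Whitney) formula; AUPR is
non-interpolated average precision with tied scores treated as a single
operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .data_io import AssociationMatrix, FeatureMatrix
from .training import TrainConfig, em_fit

__all__ = [
    "FoldPlan", "MetricsReport", "make_folds", "masked_training_matrix",
    "confusion_counts", "binary_metrics", "auroc", "aupr",
    "metrics_at_specificity", "topk_true_positives", "compute_report",
    "cross_validate", "CrossValidationResult",
]

SPECIFICITY_LEVELS = (0.95, 0.99)
TOPK_CUTOFFS = (20, 40, 60, 80, 100)


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of each known positive (i, j) to one of k folds."""

    k_folds: int
    fold_assignments: dict[tuple[int, int], int]

    def fold_positives(self, fold: int) -> list[tuple[int, int]]:
        return [ij for ij, f in self.fold_assignments.items() if f == fold]


@dataclass
class MetricsReport:
    auroc: float
    aupr: float
    at_specificity: dict[float, dict[str, float]] = field(default_factory=dict)
    topk_counts: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "at_specificity": {str(k): v for k, v in self.at_specificity.items()},
            "topk_counts": {str(k): v for k, v in self.topk_counts.items()},
        }


def make_folds(Y: AssociationMatrix, k_folds: int, seed: int) -> FoldPlan:
    """Uniform random partition of the known positives into k folds
    (sizes differ by at most one)."""
    pos = [tuple(ij) for ij in Y.positives]
    if len(pos) < k_folds:
        raise ValueError(f"need at least {k_folds} positives, have {len(pos)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pos))
    assignments = {pos[idx]: int(r % k_folds) + 1 for r, idx in enumerate(order)}
    return FoldPlan(k_folds, assignments)


def masked_training_matrix(Y: AssociationMatrix, plan: FoldPlan, test_fold: int) -> AssociationMatrix:
    """Copy of Y with the test fold's positives zeroed out."""
    if not 1 <= test_fold <= plan.k_folds:
        raise ValueError(f"fold {test_fold} outside 1..{plan.k_folds}")
    values = Y.values.copy()
    for (i, j) in plan.fold_positives(test_fold):
        values[i, j] = 0.0
    return Y.copy_with(values)


def confusion_counts(scores, labels, threshold: float) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) under the rule: predicted positive iff score >= t."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    tn = int(np.sum(~pred & ~pos))
    fn = int(np.sum(~pred & pos))
    return tp, fp, tn, fn


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def binary_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, precision, F1 and MCC from a
    confusion table; any 0/0 term is defined as 0."""
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    acc = _safe_div(tp + tn, tp + tn + fp + fn)
    prec = _safe_div(tp, tp + fp)
    f1 = _safe_div(2 * prec * sens, prec + sens)
    denom = np.sqrt(float(tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "precision": prec, "f1": f1, "mcc": float(mcc)}


def auroc(scores, labels) -> float:
    """Area under the ROC curve = Mann-Whitney probability, ties count 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def aupr(scores, labels) -> float:
    """Non-interpolated average precision; tied scores form one operating
    point (so uniform scores give AUPR equal to the prevalence)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(float)
    n_pos = labels.sum()
    if n_pos == 0:
        raise ValueError("aupr requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp_cum = np.cumsum(y)
    ranks = np.arange(1, len(y) + 1)
    # last index of each tied block: the only admissible operating points
    block_end = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    tp_b = tp_cum[block_end]
    prec_b = tp_b / ranks[block_end]
    recall_b = tp_b / n_pos
    prev_recall = np.concatenate([[0.0], recall_b[:-1]])
    return float(np.sum((recall_b - prev_recall) * prec_b))


def metrics_at_specificity(scores, labels, sp_level: float) -> dict[str, float]:
    """Metrics at the smallest score threshold achieving the requested
    specificity (predicted positive iff score >= threshold)."""
    if not 0.0 < sp_level < 1.0:
        raise ValueError("sp_level must lie in (0, 1)")
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    neg = scores[labels == 0]
    if neg.size == 0 or np.sum(labels == 1) == 0:
        raise ValueError("both classes required")
    if np.all(neg == scores.max()):
        raise ValueError("specificity level unreachable: all negatives tied at the maximum score")
    uniq = np.unique(scores)  # ascending candidate thresholds
    neg_sorted = np.sort(neg)
    spec = np.searchsorted(neg_sorted, uniq, side="left") / neg.size
    ok = np.nonzero(spec >= sp_level)[0]
    # fall back to a threshold just above every score if none qualifies
    t = uniq[ok[0]] if ok.size else np.nextafter(scores.max(), np.inf)
    return binary_metrics(*confusion_counts(scores, labels, t))


def topk_true_positives(scores, labels, ks=TOPK_CUTOFFS) -> dict[int, int]:
    """True-positive counts among the k highest-scoring pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    out = {}
    for k in ks:
        if k > len(scores):
            raise ValueError(f"k={k} exceeds the {len(scores)} scored pairs")
        out[int(k)] = int(np.sum(labels[order[:k]] == 1))
    return out


def compute_report(scores, labels,
                   sp_levels=SPECIFICITY_LEVELS, ks=TOPK_CUTOFFS) -> MetricsReport:
    usable_ks = [k for k in ks if k <= len(np.asarray(scores))]
    return MetricsReport(
        auroc=auroc(scores, labels),
        aupr=aupr(scores, labels),
        at_specificity={sp: metrics_at_specificity(scores, labels, sp) for sp in sp_levels},
        topk_counts=topk_true_positives(scores, labels, usable_ks),
    )


@dataclass
class CrossValidationResult:
    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    plan: FoldPlan


def cross_validate(
    Y: AssociationMatrix,
    X_l: FeatureMatrix,
    X_d: FeatureMatrix,
    config: TrainConfig = TrainConfig(),
    k_folds: int = 5,
    seed: int = 0,
) -> CrossValidationResult:
    """Masked k-fold cross-validation over the known positives.

    Per fold: train on the masked matrix, then score the held-out
    positives against all always-zero pairs.  Metrics are reported per
    fold and on the scores pooled across folds.
    """
    plan = make_folds(Y, k_folds, seed)
    zero_mask = Y.values == 0.0
    fold_reports = []
    pooled_scores, pooled_labels = [], []
    for fold in range(1, k_folds + 1):
        Y_train = masked_training_matrix(Y, plan, fold)
        result = em_fit(Y_train, X_l, X_d, config)
        F = result.scores.values
        held_out = plan.fold_positives(fold)
        s_pos = np.array([F[i, j] for (i, j) in held_out])
        s_neg = F[zero_mask]
        scores = np.concatenate([s_pos, s_neg])
        labels = np.concatenate([np.ones(len(s_pos)), np.zeros(len(s_neg))])
        fold_reports.append(compute_report(scores, labels))
        pooled_scores.append(scores)
        pooled_labels.append(labels)
    pooled_scores = np.concatenate(pooled_scores)
    pooled_labels = np.concatenate(pooled_labels)
    pooled = compute_report(pooled_scores, pooled_labels)
    return CrossValidationResult(fold_reports, pooled, pooled_scores, pooled_labels, plan)
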