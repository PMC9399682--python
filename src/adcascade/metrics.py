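"""Evaluation: confusion metrics, AUC, cross-validation, temporal validation.

Per binary task the peel class is positive and the metrics are

    SEN = TP/(TP+FN)        SPE = TN/(TN+FP)
    ACC = (TP+TN)/total     BACC = (SEN+SPE)/2
    F1  = 2 TP/(2 TP+FP+FN)

with AUC in the Mann-Whitney formulation (ties get half credit).  In the
cascade, a task's metrics are computed on the subjects that reach its
classifier (survivors of earlier peels).  Overall accuracy is the
fraction of subjects assigned their correct 4-class label.

Cross-validation is stratified on the 4-class label; imputation,
z-scoring and SMOTE are refitted inside every training fold, and pooled
metrics come from concatenated out-of-fold predictions (micro pooling),
rebuilt from confusion counts rather than averaged fold metrics.
Rounding (half-up, 3 decimals) happens only at report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .cascade import PipelineSpec, fit_cascade, make_tasks, predict_cascade

__all__ = [
    "ConfusionCounts",
    "TaskMetrics",
    "round_half_up",
    "confusion",
    "counts_from_rates",
    "metrics_from_counts",
    "auc",
    "overall_accuracy",
    "cross_validate",
    "temporal_validate",
    "CVResult",
    "ValidationResult",
]


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding (2.5 -> 3), as used in the printed reports."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN, self.FP + other.FP, self.FN + other.FN
        )


def confusion(true_labels, predicted_labels, positive_class) -> ConfusionCounts:
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    tpos = t == positive_class
    ppos = p == positive_class
    return ConfusionCounts(
        TP=int(np.sum(tpos & ppos)),
        TN=int(np.sum(~tpos & ~ppos)),
        FP=int(np.sum(~tpos & ppos)),
        FN=int(np.sum(tpos & ~ppos)),
    )


def counts_from_rates(sen: float, spe: float, n_pos: int, n_neg: int) -> ConfusionCounts:
    """Rebuild integer confusion counts from printed SEN/SPE and class sizes."""
    TP = int(math.floor(sen * n_pos + 0.5))
    TN = int(math.floor(spe * n_neg + 0.5))
    return ConfusionCounts(TP=TP, TN=TN, FP=n_neg - TN, FN=n_pos - TP)


@dataclass
class TaskMetrics:
    """Metrics of one binary task; undefined entries are NaN and named in
    ``undefined`` rather than silently zeroed."""

    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    f1: float
    auc: float = float("nan")
    counts: ConfusionCounts | None = None
    undefined: tuple[str, ...] = ()

    def rounded(self, ndigits: int = 3) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "accuracy", "balanced_accuracy", "f1", "auc"):
            v = getattr(self, name)
            out[name] = None if isinstance(v, float) and math.isnan(v) else round_half_up(v, ndigits)
        return out


def metrics_from_counts(counts: ConfusionCounts, auc_value: float = float("nan")) -> TaskMetrics:
    undefined = []
    P = counts.TP + counts.FN
    N = counts.TN + counts.FP
    if P == 0:
        undefined.append("sensitivity")
    if N == 0:
        undefined.append("specificity")
    sen = counts.TP / P if P else float("nan")
    spe = counts.TN / N if N else float("nan")
    acc = (counts.TP + counts.TN) / counts.total if counts.total else float("nan")
    bacc = (sen + spe) / 2.0
    denom = 2 * counts.TP + counts.FP + counts.FN
    if denom == 0:
        undefined.append("f1")
    f1 = 2 * counts.TP / denom if denom else float("nan")
    if undefined:
        if "sensitivity" in undefined or "specificity" in undefined:
            undefined.append("balanced_accuracy")
    return TaskMetrics(
        sensitivity=sen,
        specificity=spe,
        accuracy=acc,
        balanced_accuracy=bacc,
        f1=f1,
        auc=auc_value,
        counts=counts,
        undefined=tuple(undefined),
    )


def auc(scores, labels) -> float:
    """Mann-Whitney AUC of scores for binary labels (1 = positive)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    r = rankdata(s)
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def overall_accuracy(true_4class, predicted_4class) -> float:
    t = np.asarray(true_4class)
    p = np.asarray(predicted_4class)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    return float(np.mean(t == p))


def _task_eval(task, true_labels, trace_entry) -> tuple[ConfusionCounts, float]:
    reaching = trace_entry["reaching"]
    if not reaching.any():
        raise ValueError(f"no subjects reach task {task.name}")
    y_true = (np.asarray(true_labels)[reaching] == task.positive).astype(int)
    y_peel = trace_entry["peel"][reaching].astype(int)
    counts = ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_peel == 1))),
        TN=int(np.sum((y_true == 0) & (y_peel == 0))),
        FP=int(np.sum((y_true == 0) & (y_peel == 1))),
        FN=int(np.sum((y_true == 1) & (y_peel == 0))),
    )
    scores = trace_entry["scores"][reaching]
    try:
        a = auc(scores, y_true)
    except ValueError:
        a = float("nan")
    return counts, a


@dataclass
class CVResult:
    fold_assignment: np.ndarray
    per_fold_counts: list[dict]
    task_metrics: dict
    overall_accuracy: float
    predictions: pd.DataFrame
    seed: int

    @property
    def pooled_counts(self) -> dict:
        return {name: m.counts for name, m in self.task_metrics.items()}


def cross_validate(
    table: pd.DataFrame, pipeline: PipelineSpec, folds: int = 10, seed: int = 0
) -> CVResult:
    """Stratified k-fold cross-validation of the full cascade.

    Every preprocessing step is refitted on each training fold; test folds
    only ever see ``predict``.  Pooled task metrics are computed from
    summed out-of-fold confusion counts and pooled peel scores.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = table["label"].to_numpy()
    class_counts = pd.Series(labels).value_counts()
    if (class_counts < folds).any():
        small = class_counts[class_counts < folds].index.tolist()
        raise ValueError(
            f"stratification error: classes {small} have fewer subjects than folds={folds}"
        )
    tasks = make_tasks(pipeline.scenario)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31 - 1))
    n = len(table)
    fold_assignment = np.full(n, -1)
    pooled_pred = np.empty(n, dtype=object)
    task_true: dict[str, list] = {t.name: [] for t in tasks}
    task_peel: dict[str, list] = {t.name: [] for t in tasks}
    task_scores: dict[str, list] = {t.name: [] for t in tasks}
    per_fold_counts = []

    for fold, (tr, te) in enumerate(skf.split(np.zeros(n), labels)):
        fold_assignment[te] = fold
        model = fit_cascade(table.iloc[tr], pipeline, seed=(seed + 6151 * fold) % (2**31 - 1))
        pred, trace = predict_cascade(model, table.iloc[te], return_trace=True)
        pooled_pred[te] = pred
        fold_counts = {}
        te_labels = labels[te]
        for task, entry in zip(tasks, trace):
            reaching = entry["reaching"]
            y_true = (te_labels[reaching] == task.positive).astype(int)
            y_peel = entry["peel"][reaching].astype(int)
            task_true[task.name].extend(y_true.tolist())
            task_peel[task.name].extend(y_peel.tolist())
            task_scores[task.name].extend(entry["scores"][reaching].tolist())
            fold_counts[task.name] = ConfusionCounts(
                TP=int(np.sum((y_true == 1) & (y_peel == 1))),
                TN=int(np.sum((y_true == 0) & (y_peel == 0))),
                FP=int(np.sum((y_true == 0) & (y_peel == 1))),
                FN=int(np.sum((y_true == 1) & (y_peel == 0))),
            )
        per_fold_counts.append(fold_counts)

    task_metrics = {}
    for task in tasks:
        yt = np.asarray(task_true[task.name])
        yp = np.asarray(task_peel[task.name])
        counts = ConfusionCounts(
            TP=int(np.sum((yt == 1) & (yp == 1))),
            TN=int(np.sum((yt == 0) & (yp == 0))),
            FP=int(np.sum((yt == 0) & (yp == 1))),
            FN=int(np.sum((yt == 1) & (yp == 0))),
        )
        try:
            a = auc(task_scores[task.name], yt)
        except ValueError:
            a = float("nan")
        task_metrics[task.name] = metrics_from_counts(counts, auc_value=a)

    predictions = pd.DataFrame(
        {
            "subject_id": table["subject_id"].to_numpy()
            if "subject_id" in table.columns
            else np.arange(n),
            "true_label": labels,
            "predicted_label": pooled_pred.astype(str),
            "fold": fold_assignment,
        }
    )
    return CVResult(
        fold_assignment=fold_assignment,
        per_fold_counts=per_fold_counts,
        task_metrics=task_metrics,
        overall_accuracy=overall_accuracy(labels, pooled_pred.astype(str)),
        predictions=predictions,
        seed=seed,
    )


@dataclass
class ValidationResult:
    task_metrics: dict
    overall_accuracy: float
    predictions: pd.DataFrame
    model: object = field(repr=False, default=None)


def temporal_validate(
    dev_table: pd.DataFrame,
    val_table: pd.DataFrame,
    pipeline: PipelineSpec,
    seed: int = 0,
) -> ValidationResult:
    """Fit once on the development table, evaluate blind on the validation table.

    The validation rows influence nothing about the fitted model; per-task
    metrics use the survivor convention (subjects reaching each classifier).
    """
    model = fit_cascade(dev_table, pipeline, seed=seed)
    missing_cols = [c for c in model.columns if c not in val_table.columns]
    if missing_cols:
        raise ValueError(f"validation table missing manifest columns {missing_cols}")
    pred, trace = predict_cascade(model, val_table, return_trace=True)
    val_labels = val_table["label"].to_numpy()
    task_metrics = {}
    for task, entry in zip(model.tasks, trace):
        counts, a = _task_eval(task, val_labels, entry)
        task_metrics[task.name] = metrics_from_counts(counts, auc_value=a)
    predictions = pd.DataFrame(
        {
            "subject_id": val_table["subject_id"].to_numpy()
            if "subject_id" in val_table.columns
            else np.arange(len(val_table)),
            "true_label": val_labels,
            "predicted_label": pred,
        }
    )
    return ValidationResult(
        task_metrics=task_metrics,
        overall_accuracy=overall_accuracy(val_labels, pred),
        predictions=predictions,
        model=model,
    )
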