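"""Classification metrics, paired model comparison and the placement ablation.

Per-class precision, recall and F1 are one-vs-rest quantities computed
from the confusion matrix:

    Acc = (TP + TN) / (TP + TN + FP + FN)
    Pre = TP / (TP + FP)
    Rec = TP / (TP + FN)
    F1  = 2 * Pre * Rec / (Pre + Rec)

Macro averages (unweighted class means) are the headline aggregate;
micro averages are reported alongside.  When a denominator is zero the
metric is defined as 0 and flagged.

Repeated paired runs of two models are compared with a paired t test on
the per-run metric differences, with a two-sided p-value and the 95%
confidence interval for the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "PairedTestResult",
    "DegeneratePairsError",
    "confusion_matrix",
    "metrics_from_confusion",
    "evaluate_predictions",
    "paired_t_test",
    "ablation_att_placement",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) ints, rows true, columns predicted

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (arr < 0).any():
            raise ValueError("confusion matrix counts must be nonnegative")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    per_class_precision: tuple[float, ...]
    per_class_recall: tuple[float, ...]
    per_class_f1: tuple[float, ...]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    confusion: ConfusionMatrix
    zero_division_flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_precision": list(self.per_class_precision),
            "per_class_recall": list(self.per_class_recall),
            "per_class_f1": list(self.per_class_f1),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "micro_f1": self.micro_f1,
            "confusion": self.confusion.counts.tolist(),
            "zero_division_flags": list(self.zero_division_flags),
        }


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    mean_difference: float
    ci95: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
            "mean_difference": self.mean_difference,
            "ci95": list(self.ci95),
        }


class DegeneratePairsError(ValueError):
    """Raised when all paired differences are equal (zero sample sd)."""


def confusion_matrix(y_true, y_pred, num_classes: int) -> ConfusionMatrix:
    """counts[i, j] = number of items with true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} contains labels outside [0, {num_classes})")
    counts = np.bincount(y_true * num_classes + y_pred,
                         minlength=num_classes * num_classes)
    return ConfusionMatrix(counts.reshape(num_classes, num_classes))


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    k = counts.shape[0]
    tp = np.diag(counts).astype(np.float64)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp

    flags = []
    precision = np.zeros(k)
    recall = np.zeros(k)
    f1 = np.zeros(k)
    for i in range(k):
        if tp[i] + fp[i] > 0:
            precision[i] = tp[i] / (tp[i] + fp[i])
        else:
            flags.append(f"class {i}: precision undefined (never predicted)")
        if tp[i] + fn[i] > 0:
            recall[i] = tp[i] / (tp[i] + fn[i])
        else:
            flags.append(f"class {i}: recall undefined (never present)")
        if precision[i] + recall[i] > 0:
            f1[i] = 2 * precision[i] * recall[i] / (precision[i] + recall[i])

    micro_tp, micro_fp, micro_fn = tp.sum(), fp.sum(), fn.sum()
    micro_p = micro_tp / (micro_tp + micro_fp) if micro_tp + micro_fp else 0.0
    micro_r = micro_tp / (micro_tp + micro_fn) if micro_tp + micro_fn else 0.0
    micro_f = (2 * micro_p * micro_r / (micro_p + micro_r)
               if micro_p + micro_r else 0.0)
    return MetricsReport(
        accuracy=float(tp.sum() / total),
        per_class_precision=tuple(precision),
        per_class_recall=tuple(recall),
        per_class_f1=tuple(f1),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        micro_precision=float(micro_p),
        micro_recall=float(micro_r),
        micro_f1=float(micro_f),
        confusion=cm,
        zero_division_flags=tuple(flags),
    )


def evaluate_predictions(y_true, y_pred, num_classes: int) -> MetricsReport:
    return metrics_from_confusion(confusion_matrix(y_true, y_pred, num_classes))


def paired_t_test(metric_a, metric_b, confidence: float = 0.95) -> PairedTestResult:
    """Paired t test on differences ``b - a`` (b = variant, a = baseline)."""
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegeneratePairsError(
            "all paired differences are identical; the t statistic is undefined")
    mean = d.mean()
    se = sd / np.sqrt(n)
    t_stat = mean / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    q = stats.t.ppf(0.5 + confidence / 2.0, df)
    return PairedTestResult(t_statistic=float(t_stat), degrees_of_freedom=df,
                            p_value=float(p), mean_difference=float(mean),
                            ci95=(float(mean - q * se), float(mean + q * se)))


@dataclass(frozen=True)
class AblationRow:
    placement: tuple[int, ...]
    parameter_count: int
    report: MetricsReport


def ablation_att_placement(placements, model_factory, split, train_config,
                           fit_fn=None) -> list[AblationRow]:
    """Train/evaluate one model per attention-placement set under identical
    data and seeds.

    ``model_factory(placement)`` builds a model whose attention layers sit
    at the 1-indexed stages in ``placement``; ``fit_fn`` defaults to
    :func:`swinatt.train.fit` followed by test-set evaluation.
    """
    from .train import evaluate_model, fit

    rows: list[AblationRow] = []
    for placement in placements:
        placement = tuple(sorted(placement))
        model = model_factory(placement)
        if fit_fn is not None:
            report = fit_fn(model, split, train_config)
        else:
            model, _ = fit(model, split, train_config)
            report = evaluate_model(model, split.test, train_config)
        rows.append(AblationRow(placement=placement,
                                parameter_count=model.num_parameters(),
                                report=report))
    return rows
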