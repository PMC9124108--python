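"""Confusion-matrix metrics and seeded evaluation protocols.

For a binary problem, each class k in {0, 1} is treated in turn as positive
and scored with accuracy, recall (sensitivity), specificity, precision,
F-score (harmonic mean of precision and recall) and G-measure (geometric mean
of precision and recall, sqrt(P*R)).  The macro report is the unweighted mean
of each per-class metric; accuracy is by construction identical for both
classes, and specificity of class k equals recall of class 1-k.

Two protocols are provided: stratified k-fold cross-validation with a pooled
confusion matrix, and a single stratified holdout split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .datasets import ExpressionDataset
from .exceptions import InvalidConfigError, InvalidInputError, UndefinedMetricError

__all__ = [
    "ConfusionMatrix2x2",
    "ClassMetrics",
    "MetricsReport",
    "confusion",
    "class_metrics",
    "macro_average",
    "stratified_kfold",
    "evaluate",
    "round_percent",
    "format_report",
    "report_as_dict",
]

_METRIC_NAMES = ("accuracy", "recall", "specificity", "precision", "f_score", "g_measure")


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts n[actual][predicted] for binary labels."""

    counts: tuple

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        if arr.shape != (2, 2) or (arr < 0).any():
            raise InvalidInputError("confusion counts must form a non-negative 2x2 table")
        if arr.sum() == 0:
            raise InvalidInputError("confusion matrix is empty")
        object.__setattr__(self, "counts", tuple(map(tuple, arr.tolist())))

    @classmethod
    def from_counts(cls, n00: int, n01: int, n10: int, n11: int) -> "ConfusionMatrix2x2":
        """Row-major counts: n00 = actual 0 predicted 0, n01 = actual 0 predicted 1..."""
        return cls(((n00, n01), (n10, n11)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def total(self) -> int:
        return int(self.as_array().sum())


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class metrics as raw fractions in [0,1]."""

    accuracy: float
    recall: float
    specificity: float
    precision: float
    f_score: float
    g_measure: float
    precision_undefined: bool = False

    def as_percent(self) -> dict:
        return {m: round_percent(getattr(self, m)) for m in _METRIC_NAMES}


@dataclass(frozen=True)
class MetricsReport:
    """Per-class metrics plus their unweighted macro average."""

    per_class: dict
    macro: ClassMetrics


def round_percent(fraction: float) -> float:
    """Fraction -> percent, rounded half-up to 2 decimals (display convention)."""
    return float(Decimal(repr(fraction * 100.0)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def confusion(y_true, y_pred) -> ConfusionMatrix2x2:
    """Tally the 2x2 table of (actual, predicted) pairs."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise InvalidInputError("cannot build a confusion matrix from empty vectors")
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("label vectors must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not set(np.unique(arr).tolist()) <= {0, 1}:
            raise InvalidInputError(f"{name} contains labels outside {{0,1}}")
    counts = np.zeros((2, 2), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix2x2(tuple(map(tuple, counts.tolist())))


def class_metrics(cm: ConfusionMatrix2x2, k: int) -> ClassMetrics:
    """Metrics treating class ``k`` as positive.

    Precision is undefined when nothing is predicted positive; it is reported
    as 0 with ``precision_undefined=True`` so macro averages stay defined.
    Recall is undefined (error) when class k has no actual samples.
    """
    if k not in (0, 1):
        raise InvalidInputError("class index must be 0 or 1")
    n = cm.as_array()
    tp = n[k, k]
    fn = n[k, 1 - k]
    fp = n[1 - k, k]
    tn = n[1 - k, 1 - k]
    if tp + fn == 0:
        raise UndefinedMetricError(f"class {k} has no actual samples; recall undefined")
    accuracy = (tp + tn) / cm.total
    recall = tp / (tp + fn)
    specificity = tn / (tn + fp) if (tn + fp) > 0 else 1.0
    precision_undefined = (tp + fp) == 0
    precision = 0.0 if precision_undefined else tp / (tp + fp)
    f_score = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    g_measure = float(np.sqrt(precision * recall))
    return ClassMetrics(
        accuracy=float(accuracy),
        recall=float(recall),
        specificity=float(specificity),
        precision=float(precision),
        f_score=float(f_score),
        g_measure=float(g_measure),
        precision_undefined=precision_undefined,
    )


def macro_average(cm: ConfusionMatrix2x2) -> MetricsReport:
    """Unweighted mean of each per-class metric over k in {0, 1}."""
    per_class = {k: class_metrics(cm, k) for k in (0, 1)}
    macro = ClassMetrics(
        **{
            m: float(np.mean([getattr(per_class[k], m) for k in (0, 1)]))
            for m in _METRIC_NAMES
        },
        precision_undefined=any(per_class[k].precision_undefined for k in (0, 1)),
    )
    return MetricsReport(per_class=per_class, macro=macro)


def stratified_kfold(ds_or_labels, k: int, seed: int = 0) -> list[tuple]:
    """Seeded stratified k-fold indices: list of (train_idx, test_idx).

    Folds partition all samples; per-fold class counts deviate from exact
    proportionality by at most 1.  If a class has fewer than ``k`` members a
    plain shuffled k-fold is used with a warning (best effort).
    """
    labels = (
        ds_or_labels.labels
        if isinstance(ds_or_labels, ExpressionDataset)
        else np.asarray(ds_or_labels, dtype=int)
    )
    n = len(labels)
    if k < 2 or k > n:
        raise InvalidConfigError(f"fold count k={k} must lie in [2, n={n}]")
    min_class = np.bincount(labels, minlength=2).min()
    if min_class < k:
        warnings.warn(
            f"smallest class has {min_class} < k={k} samples; "
            "falling back to unstratified shuffled folds",
            stacklevel=2,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(np.zeros(n))]
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(n), labels)]


def evaluate(
    ds: ExpressionDataset,
    fit_predict,
    protocol: str = "kfold",
    k: int = 10,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[MetricsReport, ConfusionMatrix2x2]:
    """Run a train/predict callable under a seeded protocol.

    ``fit_predict(train_ds, X_test, fold)`` must return predicted 0/1 labels
    for the held-out rows.  With ``protocol="kfold"`` predictions from all
    folds are pooled into one confusion matrix; with ``protocol="holdout"``
    a single stratified split with the given test fraction is used.
    """
    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []
    if protocol == "kfold":
        folds = stratified_kfold(ds, k, seed)
    elif protocol == "holdout":
        idx = np.arange(ds.n_samples)
        tr, te = train_test_split(
            idx, test_size=test_fraction, stratify=ds.labels, random_state=seed
        )
        folds = [(tr, te)]
    else:
        raise InvalidConfigError(f"unknown protocol {protocol!r}")
    for fold, (tr, te) in enumerate(folds):
        train_ds = ds.select_samples(tr)
        y_pred = np.asarray(fit_predict(train_ds, ds.values[te], fold), dtype=int)
        y_true_all.append(ds.labels[te])
        y_pred_all.append(y_pred)
    cm = confusion(np.concatenate(y_true_all), np.concatenate(y_pred_all))
    return macro_average(cm), cm


def format_report(report: MetricsReport, cm: ConfusionMatrix2x2 | None = None) -> str:
    """Human-readable per-class + average table, percentages to 2 decimals."""
    header = f"{'Class labels':<14}" + "".join(
        f"{name:>13}" for name in ("Accuracy", "Recall", "Specificity",
                                   "Precision", "F-score", "G-measure")
    )
    lines = [header]
    for k in (0, 1):
        pc = report.per_class[k].as_percent()
        lines.append(
            f"{f'Class {k}':<14}" + "".join(f"{pc[m]:>13.2f}" for m in _METRIC_NAMES)
        )
    mac = report.macro.as_percent()
    lines.append(f"{'Average':<14}" + "".join(f"{mac[m]:>13.2f}" for m in _METRIC_NAMES))
    if cm is not None:
        arr = cm.as_array()
        lines.append("")
        lines.append("Confusion matrix (rows = actual, cols = predicted):")
        lines.append(f"  [[{arr[0,0]:>4} {arr[0,1]:>4}]")
        lines.append(f"   [{arr[1,0]:>4} {arr[1,1]:>4}]]")
    return "\n".join(lines)


def report_as_dict(report: MetricsReport, percent: bool = True) -> dict:
    """Machine-readable report (used for JSON output)."""
    conv = (lambda v: round_percent(v)) if percent else float
    out = {
        f"class_{k}": {m: conv(getattr(report.per_class[k], m)) for m in _METRIC_NAMES}
        for k in (0, 1)
    }
    out["macro"] = {m: conv(getattr(report.macro, m)) for m in _METRIC_NAMES}
    return out
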