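"""Confusion-matrix metrics, model comparison, and the paired t-test.

Accuracy is the confusion-matrix trace over the total count; per-class
precision, recall and F1 come from the one-vs-rest true/false
positive/negative counts, and the summary values are their unweighted
(macro) class means unless weighted averaging is requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split

from .errors import ConfigurationError, DegenerateVarianceError, InputError
from .features import FeatureMatrix
from . import meet

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "TTestResult",
    "confusion",
    "metrics",
    "paired_t_test",
    "compare_models",
]


@dataclass
class ConfusionMatrix:
    """Count matrix with rows = actual label, columns = predicted label."""

    counts: np.ndarray
    class_order: tuple[int, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.class_order)
        if self.counts.shape != (n, n):
            raise InputError("counts must be square and match class_order")
        if (self.counts < 0).any():
            raise InputError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        idx = pd.Index(self.class_order, name="actual")
        cols = pd.Index(self.class_order, name="predicted")
        return pd.DataFrame(self.counts, index=idx, columns=cols)


def confusion(y_true, y_pred, class_order) -> ConfusionMatrix:
    """Tally predictions into an actual-by-predicted count matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InputError("y_true and y_pred must have equal length")
    order = [int(c) for c in class_order]
    known = set(order)
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        unknown = set(int(v) for v in np.unique(y)) - known
        if unknown:
            raise InputError(f"{name} contains labels outside class_order: {sorted(unknown)}")
    counts = _sk_confusion(y_true, y_pred, labels=order)
    return ConfusionMatrix(counts=counts, class_order=tuple(order))


@dataclass
class MetricsReport:
    """Accuracy plus per-class and averaged precision/recall/F1."""

    accuracy: float
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    support: dict[int, int]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    average: str = "macro"

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "average": self.average,
            "per_class": {
                str(c): {
                    "precision": self.precision[c],
                    "recall": self.recall[c],
                    "f1": self.f1[c],
                    "support": self.support[c],
                }
                for c in self.precision
            },
        }


def metrics(cm: ConfusionMatrix, average: str = "macro") -> MetricsReport:
    """Metric report from a confusion matrix.

    Classes that were never predicted get precision 0 with a logged
    warning.  ``average`` selects macro (unweighted) or support-weighted
    summary values.
    """
    if average not in ("macro", "weighted"):
        raise ConfigurationError(f"unknown averaging {average!r}")
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise InputError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    pred_pos = counts.sum(axis=0).astype(float)
    actual_pos = counts.sum(axis=1).astype(float)
    never_predicted = [c for c, p in zip(cm.class_order, pred_pos) if p == 0]
    if never_predicted:
        log.warning("classes never predicted, precision set to 0: %s", never_predicted)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(pred_pos > 0, tp / pred_pos, 0.0)
        rec = np.where(actual_pos > 0, tp / actual_pos, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    if average == "macro":
        weights = np.full(len(cm.class_order), 1.0 / len(cm.class_order))
    else:
        weights = actual_pos / total
    return MetricsReport(
        accuracy=float(tp.sum() / total),
        precision={c: float(p) for c, p in zip(cm.class_order, prec)},
        recall={c: float(r) for c, r in zip(cm.class_order, rec)},
        f1={c: float(v) for c, v in zip(cm.class_order, f1)},
        support={c: int(s) for c, s in zip(cm.class_order, actual_pos)},
        macro_precision=float((weights * prec).sum()),
        macro_recall=float((weights * rec).sum()),
        macro_f1=float((weights * f1).sum()),
        average=average,
    )


@dataclass(frozen=True)
class TTestResult:
    """Two-tailed paired Student t-test over matched score pairs."""

    t_statistic: float
    p_value: float
    degrees_of_freedom: int
    pair_labels: tuple[str, str] = ("a", "b")

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "degrees_of_freedom": self.degrees_of_freedom,
            "pair_labels": list(self.pair_labels),
        }


def paired_t_test(acc_a, acc_b, pair_labels=("a", "b")) -> TTestResult:
    """Paired two-tailed t-test on matched per-subject scores.

    t = mean(d) / (sd(d)/sqrt(n)) with d = a - b and sample sd (n-1); the
    p-value comes from Student's t with n-1 degrees of freedom.
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise InputError("need two equal-length score vectors with n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise DegenerateVarianceError(
            "all paired differences are identical; the t statistic is undefined"
        )
    res = stats.ttest_rel(a, b)
    return TTestResult(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        degrees_of_freedom=a.size - 1,
        pair_labels=tuple(pair_labels),
    )


def stratified_split(
    features: FeatureMatrix, train_fraction: float = 0.7, seed: int = 0
):
    """Class-stratified train/test split of a feature matrix."""
    if not 0 < train_fraction < 1:
        raise ConfigurationError(
            f"train_fraction must lie strictly in (0, 1), got {train_fraction}"
        )
    idx = np.arange(len(features))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        random_state=seed,
        stratify=features.labels,
        shuffle=True,
    )
    classes = set(features.labels.tolist())
    for name, part in (("train", train_idx), ("test", test_idx)):
        present = set(features.labels[part].tolist())
        if present != classes:
            raise ConfigurationError(
                f"class missing from the {name} split: {sorted(classes - present)}"
            )
    return train_idx, test_idx


def compare_models(
    features: FeatureMatrix,
    model_specs: dict | None = None,
    split: float = 0.7,
    seed: int = 0,
    a: int = 2,
    hyperparams: dict | None = None,
    average: str = "macro",
) -> dict[str, MetricsReport]:
    """Train the given models on a shared stratified split and score them.

    ``model_specs`` maps a name to either the string ``"meet"``, the string
    ``"et"`` (the gate-family Extra-Trees baseline trained on all classes),
    or a scikit-learn classifier factory ``lambda seed: estimator``.  MEET
    and the ET baseline are always included.
    """
    specs: dict = {"meet": "meet", "et": "et"}
    specs.update(model_specs or {})
    train_idx, test_idx = stratified_split(features, split, seed)
    X_tr, y_tr = features.values[train_idx], features.labels[train_idx]
    X_te, y_te = features.values[test_idx], features.labels[test_idx]
    class_order = tuple(int(c) for c in np.unique(features.labels))

    reports: dict[str, MetricsReport] = {}
    for name, spec in specs.items():
        if spec == "meet":
            model = meet.fit(X_tr, a=a, hyperparams=hyperparams, seed=seed, labels=y_tr)
            y_pred = meet.predict(model, X_te)
        elif spec == "et":
            clf = meet._seeded_tree_ensemble(
                dict(meet.DEFAULT_HYPERPARAMS, **(hyperparams or {})), [seed, 2]
            )
            clf.fit(X_tr, y_tr)
            y_pred = clf.predict(X_te)
        else:
            clf = spec(seed) if callable(spec) else spec
            clf.fit(X_tr, y_tr)
            y_pred = clf.predict(X_te)
        reports[name] = metrics(confusion(y_te, y_pred, class_order), average=average)
    return reports
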