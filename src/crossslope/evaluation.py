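"""Cross-validation and train/test evaluation of the terrain classifier.

Accuracy is the number of mid-swing windows whose terrain was predicted
correctly divided by the number of windows evaluated; per-class accuracies
and their (min, max) range accompany every confusion matrix. LOOCV leaves
out one *trial* at a time by default: overlapping windows within a trial
are near-duplicates, so window-level folds would leak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gait_data import (
    Dataset,
    DataError,
    SchemaError,
    TERRAIN_ORDER,
)
from .features import FeatureMatrix, build_feature_matrix, restrict_to_signals
from .lda import fit_lda, predict
from .windowing import WindowSpec

__all__ = [
    "ConfusionMatrix",
    "AccuracyReport",
    "confusion_matrix",
    "accuracy_report",
    "loocv",
    "evaluate_on_test",
]

_TERRAIN_LABELS = [t.label for t in TERRAIN_ORDER]


@dataclass
class ConfusionMatrix:
    """K×K counts; rows = true terrain, columns = predicted terrain."""

    counts: np.ndarray
    class_order: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        K = len(self.class_order)
        if self.counts.shape != (K, K):
            raise ValueError("confusion matrix shape must match class order")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_order != other.class_order:
            raise ValueError("class orders differ")
        return ConfusionMatrix(self.counts + other.counts, list(self.class_order))

    def to_dict(self) -> dict:
        return {"class_order": self.class_order, "counts": self.counts.tolist()}


@dataclass
class AccuracyReport:
    overall: float
    per_class: dict[str, float]
    per_class_range: tuple[float, float]
    error: float
    n_windows: int
    fold_errors: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "per_class": self.per_class,
            "per_class_range": list(self.per_class_range),
            "error": self.error,
            "n_windows": self.n_windows,
            "fold_errors": self.fold_errors,
        }


def confusion_matrix(
    true_labels, predicted_labels, class_order: list[str] | None = None
) -> ConfusionMatrix:
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"{len(true_labels)} true vs {len(predicted_labels)} predicted labels"
        )
    if class_order is None:
        class_order = list(_TERRAIN_LABELS)
    index = {c: i for i, c in enumerate(class_order)}
    unknown = {c for c in true_labels + predicted_labels} - set(index)
    if unknown:
        raise ValueError(f"labels outside class order: {sorted(unknown)}")
    K = len(class_order)
    counts = np.zeros((K, K), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(class_order))


def accuracy_report(cm: ConfusionMatrix, fold_errors: list[str] | None = None) -> AccuracyReport:
    total = cm.total
    if total == 0:
        raise DataError("empty confusion matrix")
    overall = float(np.trace(cm.counts)) / total
    per_class = {}
    rates = []
    for i, c in enumerate(cm.class_order):
        row = cm.row_sums[i]
        if row > 0:
            rate = float(cm.counts[i, i]) / float(row)
            per_class[c] = rate
            rates.append(rate)
    return AccuracyReport(
        overall=overall,
        per_class=per_class,
        per_class_range=(min(rates), max(rates)),
        error=1.0 - overall,
        n_windows=total,
        fold_errors=fold_errors or [],
    )


def _as_matrix(data, signals, spec: WindowSpec | None) -> FeatureMatrix:
    if isinstance(data, Dataset):
        from .gait_data import SignalInventory

        inv = SignalInventory(
            tuple(
                s
                for s in SignalInventory.full_with_ips().signals
                if s.name in data.signal_names
            )
        )
        data = build_feature_matrix(data, inv, spec or WindowSpec())
    if not isinstance(data, FeatureMatrix):
        raise TypeError("expected a Dataset or FeatureMatrix")
    if signals is not None:
        data = restrict_to_signals(data, signals)
    return data


def loocv(
    data,
    signals=None,
    shrinkage: float = 1e-4,
    unit: str = "trial",
    priors: str = "empirical",
    spec: WindowSpec | None = None,
) -> tuple[ConfusionMatrix, AccuracyReport]:
    """Leave-one-unit-out cross-validation over a dataset or feature matrix.

    ``unit='trial'`` (default) holds out all windows of one trial per fold;
    ``unit='window'`` holds out single windows (available for comparison,
    optimistic under overlapping windows). Folds whose training part lacks
    a class are skipped and recorded in the report's ``fold_errors``.
    """
    matrix = _as_matrix(data, signals, spec)
    if unit == "trial":
        groups = matrix.trials
    elif unit == "window":
        groups = np.arange(len(matrix))
    else:
        raise ValueError("unit must be 'trial' or 'window'")
    unique_groups = list(dict.fromkeys(groups))
    if len(unique_groups) < 2:
        raise DataError("need at least 2 cross-validation units")

    class_order = [c for c in _TERRAIN_LABELS if c in set(matrix.y)]
    total = np.zeros((len(class_order), len(class_order)), dtype=int)
    fold_errors: list[str] = []
    for g in unique_groups:
        held = groups == g
        train = matrix.select_rows(~held)
        test = matrix.select_rows(held)
        if set(class_order) - set(train.y):
            fold_errors.append(
                f"fold {g!r}: training part lacks class "
                f"{sorted(set(class_order) - set(train.y))}; skipped"
            )
            continue
        model = fit_lda(train, shrinkage=shrinkage, priors=priors)
        pred = predict(model, test)
        total += confusion_matrix(test.y, pred, class_order).counts
    cm = ConfusionMatrix(total, class_order)
    return cm, accuracy_report(cm, fold_errors)


def evaluate_on_test(
    train,
    test,
    signals=None,
    shrinkage: float = 1e-4,
    priors: str = "empirical",
    spec: WindowSpec | None = None,
) -> tuple[ConfusionMatrix, AccuracyReport]:
    """Single fit on all training windows, evaluated on all test windows."""
    train_m = _as_matrix(train, signals, spec)
    test_m = _as_matrix(test, signals, spec)
    if train_m.feature_names != test_m.feature_names:
        raise SchemaError("train and test feature columns differ")
    if len(test_m) == 0:
        raise DataError("empty test set")
    model = fit_lda(train_m, shrinkage=shrinkage, priors=priors)
    pred = predict(model, test_m)
    class_order = [c for c in _TERRAIN_LABELS if c in set(train_m.y) | set(test_m.y)]
    cm = confusion_matrix(test_m.y, pred, class_order)
    return cm, accuracy_report(cm)
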