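"""Sequential forward/backward signal selection (wrapper selection).

Selection operates at the granularity of the *signal*: a signal's 2 or 4
window statistics enter or leave the classifier together. SFS grows the
signal set greedily, at each step adding the signal whose addition gives
the most accurate classifier; SBS shrinks from the full set, removing the
signal whose removal leaves the most accurate classifier (i.e. the least
useful signal). Candidate accuracy is scored either by leave-one-trial-out
cross-validation on the training data or on a fixed held-out dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .gait_data import DataError
from .features import FeatureMatrix
from .evaluation import evaluate_on_test, loocv

__all__ = ["EvalProtocol", "SelectionStep", "SelectionTrace", "sfs", "sbs",
           "accuracy_vs_count_curve"]


@dataclass(frozen=True)
class EvalProtocol:
    """How candidate signal sets are scored during selection.

    ``loocv_training``: leave-one-trial-out on the training matrix.
    ``fixed_test``: single fit on training, scored on ``pick_matrix``.
    """

    kind: str = "loocv_training"
    pick_matrix: FeatureMatrix | None = None
    loocv_unit: str = "trial"

    def __post_init__(self) -> None:
        if self.kind not in ("loocv_training", "fixed_test"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "fixed_test" and self.pick_matrix is None:
            raise ValueError("fixed_test protocol requires a pick_matrix")

    def score(self, train: FeatureMatrix, signals, shrinkage: float):
        if self.kind == "loocv_training":
            _, report = loocv(
                train, signals=signals, shrinkage=shrinkage, unit=self.loocv_unit
            )
        else:
            _, report = evaluate_on_test(
                train, self.pick_matrix, signals=signals, shrinkage=shrinkage
            )
        return report


@dataclass(frozen=True)
class SelectionStep:
    signal: str  # signal added (SFS) or removed (SBS) at this step
    n_signals: int  # size of the evaluated set after the step
    accuracy: float
    per_class_range: tuple[float, float]


@dataclass
class SelectionTrace:
    """Ordered ranking with the accuracy reached at each step."""

    method: str  # "SFS" or "SBS"
    steps: list[SelectionStep]
    ranking: list[str]  # rank 1 first
    inventory_names: list[str] = field(default_factory=list)

    def accuracies(self) -> list[float]:
        return [s.accuracy for s in self.steps]

    def top(self, k: int) -> list[str]:
        return self.ranking[:k]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, sig in enumerate(self.ranking, start=1):
            step = next((s for s in self.steps if s.signal == sig), None)
            rows.append(
                {
                    "rank": rank,
                    "signal": sig,
                    "accuracy": step.accuracy if step else float("nan"),
                    "per_class_min": step.per_class_range[0] if step else float("nan"),
                    "per_class_max": step.per_class_range[1] if step else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def _check(train: FeatureMatrix) -> list[str]:
    names = list(train.inventory.names)
    if len(names) < 2:
        raise DataError("selection needs at least 2 signals")
    if len(set(train.y)) < 2:
        raise DataError("selection needs at least 2 classes in the training data")
    return names


def sfs(
    train: FeatureMatrix,
    protocol: EvalProtocol = EvalProtocol(),
    shrinkage: float = 1e-4,
) -> SelectionTrace:
    """Sequential forward selection over the matrix's inventory.

    Ties in candidate accuracy break toward the lowest inventory index, so
    the trace is deterministic.
    """
    names = _check(train)
    remaining = list(names)
    chosen: list[str] = []
    steps: list[SelectionStep] = []
    while remaining:
        best = None
        for cand in remaining:  # inventory order → ties favor lowest index
            report = protocol.score(train, chosen + [cand], shrinkage)
            if best is None or report.overall > best[1].overall:
                best = (cand, report)
        cand, report = best
        chosen.append(cand)
        remaining.remove(cand)
        steps.append(
            SelectionStep(
                signal=cand,
                n_signals=len(chosen),
                accuracy=report.overall,
                per_class_range=report.per_class_range,
            )
        )
    return SelectionTrace("SFS", steps, list(chosen), list(names))


def sbs(
    train: FeatureMatrix,
    protocol: EvalProtocol = EvalProtocol(),
    shrinkage: float = 1e-4,
) -> SelectionTrace:
    """Sequential backward selection: greedy elimination down to one signal.

    The ranking lists the last survivor first, then signals in reverse
    removal order (removed last = more useful).
    """
    names = _check(train)
    surviving = list(names)
    removed: list[str] = []
    steps: list[SelectionStep] = []
    while len(surviving) > 1:
        best = None
        for cand in surviving:  # inventory order → ties favor lowest index
            rest = [s for s in surviving if s != cand]
            report = protocol.score(train, rest, shrinkage)
            if best is None or report.overall > best[1].overall:
                best = (cand, report)
        cand, report = best
        surviving.remove(cand)
        removed.append(cand)
        steps.append(
            SelectionStep(
                signal=cand,
                n_signals=len(surviving),
                accuracy=report.overall,
                per_class_range=report.per_class_range,
            )
        )
    ranking = list(surviving) + list(reversed(removed))
    return SelectionTrace("SBS", steps, ranking, list(names))


def accuracy_vs_count_curve(
    trace: SelectionTrace,
    train: FeatureMatrix,
    measure: dict[str, object],
    shrinkage: float = 1e-4,
    loocv_unit: str = "trial",
) -> pd.DataFrame:
    """Accuracy of each nested signal set on one or more measure datasets.

    ``measure`` maps a column name to either the string ``"loocv"`` (score
    by leave-one-trial-out on the training matrix) or a held-out
    FeatureMatrix. For an SFS trace the nested sets are the ranking
    prefixes (1..N signals); for SBS they are the surviving sets of each
    elimination step (N−1..1) plus the full set, which makes the two
    curves directly comparable on a signals-used axis.
    """
    n = len(trace.ranking)
    if trace.method == "SFS":
        sets = [trace.ranking[:k] for k in range(1, n + 1)]
    else:
        sets = [trace.ranking[:k] for k in range(n, 0, -1)]
    rows = []
    for sigs in sets:
        row: dict[str, object] = {"n_signals": len(sigs), "signals": ",".join(sigs)}
        for name, target in measure.items():
            if isinstance(target, str) and target == "loocv":
                _, rep = loocv(train, signals=sigs, shrinkage=shrinkage, unit=loocv_unit)
            else:
                _, rep = evaluate_on_test(train, target, signals=sigs, shrinkage=shrinkage)
            row[name] = rep.overall
        rows.append(row)
    return pd.DataFrame(rows).sort_values("n_signals", ignore_index=True)
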