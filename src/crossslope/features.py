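"""Per-window summary statistics and feature-matrix assembly.

Each mid-swing window contributes one feature vector: for every signal in
the inventory, (mean, sd, max, min) — or (mean, sd) for ground reaction
force and center-of-pressure channels — concatenated in inventory order.
The full inventory yields 124 values per window, the in-pylon-only
inventory 24.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gait_data import (
    Dataset,
    DataError,
    SchemaError,
    SignalInventory,
    StatPolicy,
    TrialRecording,
)
from .windowing import Window, WindowSpec, enumerate_windows

__all__ = [
    "STAT_ORDER",
    "window_statistics",
    "feature_columns",
    "build_feature_vector",
    "build_feature_matrix",
    "restrict_to_signals",
    "FeatureVector",
    "FeatureMatrix",
    "META_COLUMNS",
]

#: Statistic order within a signal's block.
STAT_ORDER = ("mean", "sd", "max", "min")

#: Non-feature columns of a serialized feature matrix.
META_COLUMNS = ("trial", "subject", "label", "start_ms")


def window_statistics(segment, policy: StatPolicy) -> tuple[float, ...]:
    """Summary statistics of one window's samples.

    Returns (mean, sd, max, min) for ``FOUR_STATS`` signals, (mean, sd) for
    ``TWO_STATS``. The sd is the sample standard deviation (n−1 divisor).
    """
    x = np.asarray(segment, dtype=float)
    if len(x) < 2:
        raise ValueError("window segment must contain at least 2 samples")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if policy is StatPolicy.TWO_STATS:
        return (mean, sd)
    return (mean, sd, float(x.max()), float(x.min()))


def feature_columns(inventory: SignalInventory) -> list[str]:
    """Deterministic column names: inventory order × statistic order."""
    cols = []
    for sig in inventory.signals:
        for stat in STAT_ORDER[: sig.stat_policy.n_stats]:
            cols.append(f"{sig.name}.{stat}")
    return cols


@dataclass
class FeatureVector:
    values: np.ndarray
    keys: list[str]
    window: Window
    label: str
    trial_id: str
    subject_id: str

    def __len__(self) -> int:
        return len(self.values)


def build_feature_vector(
    trial: TrialRecording, window: Window, inventory: SignalInventory
) -> FeatureVector:
    """One window's feature vector over an inventory (124 or 24 values)."""
    missing = [s.name for s in inventory.signals if s.name not in trial.series]
    if missing:
        raise SchemaError(
            f"trial {trial.trial_id!r} lacks inventory signals: {missing}"
        )
    values: list[float] = []
    for sig in inventory.signals:
        seg = trial.series[sig.name][window.start_sample : window.end_sample]
        values.extend(window_statistics(seg, sig.stat_policy))
    return FeatureVector(
        values=np.asarray(values),
        keys=feature_columns(inventory),
        window=window,
        label=trial.terrain.label,
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
    )


@dataclass
class FeatureMatrix:
    """Stacked per-window feature vectors with provenance.

    ``df`` holds the meta columns (trial, subject, label, start_ms) followed
    by one column per (signal, statistic); provenance keeps resampling
    leakage-safe (windows of one trial are near-duplicates and must move
    together across cross-validation folds).
    """

    df: pd.DataFrame
    inventory: SignalInventory

    def __post_init__(self) -> None:
        expected = list(META_COLUMNS) + feature_columns(self.inventory)
        if list(self.df.columns) != expected:
            raise SchemaError("feature matrix columns do not match inventory")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def feature_names(self) -> list[str]:
        return feature_columns(self.inventory)

    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_names].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    @property
    def trials(self) -> np.ndarray:
        return self.df["trial"].to_numpy()

    def select_rows(self, mask) -> "FeatureMatrix":
        return FeatureMatrix(self.df.loc[mask].reset_index(drop=True), self.inventory)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def build_feature_matrix(
    dataset: Dataset,
    inventory: SignalInventory,
    spec: WindowSpec = WindowSpec(),
    regions: tuple[str, ...] = ("mid_swing",),
) -> FeatureMatrix:
    """One row per mid-swing window per trial, with provenance columns.

    Trials yielding no window in the requested regions are excluded with a
    warning rather than failing the whole dataset.
    """
    records: list[dict] = []
    for trial in dataset.trials:
        rows_before = len(records)
        for window in enumerate_windows(trial, spec):
            if window.region not in regions:
                continue
            fv = build_feature_vector(trial, window, inventory)
            rec = {
                "trial": fv.trial_id,
                "subject": fv.subject_id,
                "label": fv.label,
                "start_ms": window.start_time_rel_hs_ms,
            }
            rec.update(zip(fv.keys, fv.values))
            records.append(rec)
        if len(records) == rows_before:
            warnings.warn(
                f"trial {trial.trial_id!r} produced no {'/'.join(regions)} "
                f"windows; excluded",
                stacklevel=2,
            )
    if not records:
        raise DataError("no windows extracted from dataset")
    df = pd.DataFrame.from_records(
        records, columns=list(META_COLUMNS) + feature_columns(inventory)
    )
    return FeatureMatrix(df=df, inventory=inventory)


def restrict_to_signals(matrix: FeatureMatrix, signals) -> FeatureMatrix:
    """Keep only the statistics belonging to the chosen signals (a signal's
    2 or 4 statistics always move together), preserving inventory order."""
    sub_inventory = matrix.inventory.subset(signals)
    cols = list(META_COLUMNS) + feature_columns(sub_inventory)
    return FeatureMatrix(df=matrix.df[cols].copy(), inventory=sub_inventory)
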