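"""Pooled-covariance linear discriminant analysis, written from scratch.

The classifier models each terrain class as a Gaussian with its own mean
and a shared covariance, estimated as the pooled within-class sample
covariance (divisor n − K). Classification maximizes the linear
discriminant

    δ_c(x) = xᵀ Σ_λ⁻¹ μ_c − ½ μ_cᵀ Σ_λ⁻¹ μ_c + ln π_c

with optional shrinkage Σ_λ = (1−λ) Σ + λ (tr Σ / p) I toward a spherical
target, which keeps Σ_λ positive definite when the feature count exceeds
the per-class sample count.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .gait_data import ConfigurationError, DataError, SchemaError, TERRAIN_ORDER
from .features import FeatureMatrix

__all__ = [
    "LDAModel",
    "fit_lda",
    "decision_scores",
    "predict",
    "majority_vote",
    "save_model",
    "load_model",
    "ConditioningError",
]

_TERRAIN_LABELS = [t.label for t in TERRAIN_ORDER]


class ConditioningError(DataError):
    """Pooled covariance is singular; shrinkage λ > 0 is required."""


@dataclass
class LDAModel:
    class_order: list[str]
    means: np.ndarray  # (K, p)
    pooled_cov: np.ndarray  # (p, p)
    shrinkage: float
    priors: np.ndarray  # (K,)
    feature_keys: list[str]
    scaling: tuple[np.ndarray, np.ndarray] | None = None  # (center, scale)
    _coef: np.ndarray = field(default=None, repr=False)  # (K, p), lazy
    _intercept: np.ndarray = field(default=None, repr=False)  # (K,)

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def shrunk_covariance(self) -> np.ndarray:
        p = self.pooled_cov.shape[0]
        lam = self.shrinkage
        target = (np.trace(self.pooled_cov) / p) * np.eye(p)
        return (1.0 - lam) * self.pooled_cov + lam * target

    def _ensure_coefficients(self) -> None:
        if self._coef is not None:
            return
        sigma = self.shrunk_covariance()
        try:
            cho = sla.cho_factor(sigma)
        except np.linalg.LinAlgError:
            raise ConditioningError(
                "shrunk covariance not positive definite; increase shrinkage"
            ) from None
        coef = sla.cho_solve(cho, self.means.T).T  # rows: Σ⁻¹ μ_c
        intercept = -0.5 * np.einsum("cp,cp->c", self.means, coef) + np.log(self.priors)
        self._coef = coef
        self._intercept = intercept


def _extract(matrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(matrix, FeatureMatrix):
        return matrix.X, matrix.y, matrix.feature_names
    raise TypeError("expected a FeatureMatrix; use fit_lda_arrays for raw arrays")


def _class_order_for(labels) -> list[str]:
    present = set(labels)
    if present <= set(_TERRAIN_LABELS):
        return [c for c in _TERRAIN_LABELS if c in present]
    return sorted(present)


def fit_lda_arrays(
    X,
    y,
    shrinkage: float = 1e-4,
    priors: str = "empirical",
    standardize: bool = False,
    feature_keys: list[str] | None = None,
) -> LDAModel:
    """Fit on raw arrays. Class order is the fixed terrain order
    (eversion < flush < inversion) when labels are terrain labels, else
    lexicographic; ties in prediction break toward the earlier class."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise DataError("X must be 2-D with one label per row")
    if not 0.0 <= shrinkage <= 1.0:
        raise ConfigurationError("shrinkage must lie in [0, 1]")
    class_order = _class_order_for(y)
    if len(class_order) < 2:
        raise DataError("need at least 2 classes to fit a discriminant")
    counts = Counter(y)
    thin = [c for c in class_order if counts[c] < 2]
    if thin:
        raise DataError(f"classes with <2 rows: {thin}")

    scaling = None
    if standardize:
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        X = (X - center) / scale
        scaling = (center, scale)

    n, p = X.shape
    K = len(class_order)
    means = np.empty((K, p))
    scatter = np.zeros((p, p))
    for i, c in enumerate(class_order):
        Xc = X[y == c]
        means[i] = Xc.mean(axis=0)
        d = Xc - means[i]
        scatter += d.T @ d
    pooled = scatter / (n - K)

    if priors == "empirical":
        pri = np.array([counts[c] / n for c in class_order])
    elif priors == "uniform":
        pri = np.full(K, 1.0 / K)
    else:
        raise ConfigurationError("priors must be 'empirical' or 'uniform'")

    model = LDAModel(
        class_order=list(class_order),
        means=means,
        pooled_cov=pooled,
        shrinkage=float(shrinkage),
        priors=pri,
        feature_keys=feature_keys or [f"x{i}" for i in range(p)],
        scaling=scaling,
    )
    model._ensure_coefficients()  # fail at fit time if Σ_λ is singular
    return model


def fit_lda(
    matrix: FeatureMatrix,
    shrinkage: float = 1e-4,
    priors: str = "empirical",
    standardize: bool = False,
) -> LDAModel:
    """Fit the terrain classifier on a feature matrix."""
    X, y, keys = _extract(matrix)
    return fit_lda_arrays(
        X, y, shrinkage=shrinkage, priors=priors, standardize=standardize,
        feature_keys=keys,
    )


def _prepare_rows(model: LDAModel, rows) -> np.ndarray:
    if isinstance(rows, FeatureMatrix):
        if rows.feature_names != model.feature_keys:
            raise SchemaError("feature keys do not match the fitted model")
        X = rows.X
    else:
        X = np.atleast_2d(np.asarray(rows, dtype=float))
        if X.shape[1] != model.n_features:
            raise SchemaError(
                f"expected {model.n_features} features, got {X.shape[1]}"
            )
    if model.scaling is not None:
        center, scale = model.scaling
        X = (X - center) / scale
    return X


def decision_scores(model: LDAModel, rows) -> np.ndarray:
    """Per-class discriminant values δ_c, shape (n, K)."""
    X = _prepare_rows(model, rows)
    model._ensure_coefficients()
    return X @ model._coef.T + model._intercept


def predict(model: LDAModel, rows) -> np.ndarray:
    """Argmax-δ class labels; ties break toward the earlier class in
    ``class_order`` (argmax returns the first maximum)."""
    scores = decision_scores(model, rows)
    idx = np.argmax(scores, axis=1)
    return np.asarray(model.class_order, dtype=object)[idx]


def majority_vote(labels, k: int) -> str:
    """Modal label of the last ``k`` window predictions; ties break toward
    the most recent label. Smooths per-window decisions within a stride."""
    labels = list(labels)
    if k < 1:
        raise ValueError("k must be ≥ 1")
    if len(labels) < k:
        raise ValueError(f"need at least k={k} labels, got {len(labels)}")
    recent = labels[-k:]
    counts = Counter(recent)
    top = max(counts.values())
    # scan from most recent: first label with maximal count wins ties
    for lab in reversed(recent):
        if counts[lab] == top:
            return lab
    raise AssertionError("unreachable")


def save_model(model: LDAModel, path) -> None:
    doc = {
        "class_order": model.class_order,
        "means": model.means.tolist(),
        "pooled_cov": model.pooled_cov.tolist(),
        "shrinkage": model.shrinkage,
        "priors": model.priors.tolist(),
        "feature_keys": model.feature_keys,
        "scaling": None
        if model.scaling is None
        else [model.scaling[0].tolist(), model.scaling[1].tolist()],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_model(path) -> LDAModel:
    with open(path) as fh:
        doc = json.load(fh)
    scaling = doc["scaling"]
    return LDAModel(
        class_order=doc["class_order"],
        means=np.asarray(doc["means"]),
        pooled_cov=np.asarray(doc["pooled_cov"]),
        shrinkage=doc["shrinkage"],
        priors=np.asarray(doc["priors"]),
        feature_keys=doc["feature_keys"],
        scaling=None if scaling is None else (np.asarray(scaling[0]), np.asarray(scaling[1])),
    )
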