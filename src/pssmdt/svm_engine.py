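"""Soft-margin RBF-kernel SVM training, tuning and prediction.

The classifier solves the usual soft-margin problem

    min_{w,b,xi}  (1/2) w·w + C sum_i xi_i
    s.t.          y_i (phi(x_i)·w + b) >= 1 - xi_i,  xi_i >= 0

in the dual, with the radial basis function kernel
K(x, x') = exp(-gamma ||x - x'||^2). LIBSVM (via scikit-learn's SVC) is the
solver, as is conventional for this classifier. Hyperparameters (C, gamma)
are selected by stratified 5-fold cross-validated grid search; the grids
default to the LIBSVM convention C in 2^{-5..15} (step 2^2) and gamma in
2^{-15..3} (step 2^2).

No feature scaling is applied by default; an optional min–max scaler (fit on
the training data only) is available because raw squared-PSSM features span
a large dynamic range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datasets import LabeledDataset
from .schema import DescriptorSchema, FeatureVector, SchemaError

#: LIBSVM-convention default hyperparameter grids.
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-15, 4, 2))


class TrainingError(ValueError):
    """Invalid training data or configuration."""


@dataclass(frozen=True)
class Prediction:
    """One sequence's decision value and hard label (sign; 0 ties to +1)."""

    id: str
    decision_value: float
    label: int


class RbfSvmClassifier(ClassifierMixin, BaseEstimator):
    """RBF-kernel soft-margin SVM over descriptor feature matrices.

    A thin, schema-aware wrapper around :class:`sklearn.svm.SVC` exposing the
    dual solution (support vectors, dual coefficients alpha_i * y_i, bias)
    needed by the discriminant-weight analysis.

    Parameters
    ----------
    C:
        Soft-margin penalty (> 0).
    gamma:
        RBF kernel width (> 0).
    scale:
        If true, min–max scale each feature to [0, 1] using ranges fitted on
        the training data. Off by default.
    schema:
        Optional :class:`~pssmdt.schema.DescriptorSchema`; when set, single
        feature vectors are checked against it at prediction time.

    Attributes
    ----------
    support_vectors_ : (n_sv, d) array
    dual_coef_ : (n_sv,) array of alpha_i * y_i, bounded by C in magnitude
    intercept_ : float bias b
    alpha_signed_ : (n_train,) array of alpha_i * y_i, zero off the support
    """

    def __init__(self, C: float = 1.0, gamma: float = 1.0, scale: bool = False,
                 schema: DescriptorSchema | None = None, tol: float = 1e-7):
        self.C = C
        self.gamma = gamma
        self.scale = scale
        self.schema = schema
        self.tol = tol

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y) -> "RbfSvmClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise TrainingError(f"feature matrix must be 2-D, got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            raise TrainingError("training features contain non-finite values")
        classes = set(np.unique(y))
        if not classes <= {-1, 1}:
            raise TrainingError("labels must be +1 or -1")
        if len(classes) < 2:
            raise TrainingError("training data contains a single class")
        if self.C <= 0 or self.gamma <= 0:
            raise TrainingError(f"C and gamma must be positive (C={self.C}, gamma={self.gamma})")

        if self.scale:
            lo, hi = X.min(axis=0), X.max(axis=0)
            span = np.where(hi > lo, hi - lo, 1.0)
            self.scale_offset_, self.scale_span_ = lo, span
            X = (X - lo) / span
        else:
            self.scale_offset_ = self.scale_span_ = None

        svc = SVC(C=self.C, gamma=self.gamma, kernel="rbf", tol=self.tol)
        svc.fit(X, y)
        self._svc = svc
        self.classes_ = svc.classes_
        self.n_features_in_ = X.shape[1]
        self.support_ = svc.support_
        self.support_vectors_ = svc.support_vectors_
        # SVC orders dual_coef_ by its own class order (-1 first); the stored
        # values are alpha_i * y_i already.
        self.dual_coef_ = svc.dual_coef_[0].copy()
        self.intercept_ = float(svc.intercept_[0])
        self.alpha_signed_ = np.zeros(X.shape[0])
        self.alpha_signed_[self.support_] = self.dual_coef_
        return self

    # -- prediction ---------------------------------------------------------

    def _prepare(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"feature dimension {X.shape[1]} does not match the model's "
                f"{self.n_features_in_}"
            )
        if self.scale_offset_ is not None:
            X = (X - self.scale_offset_) / self.scale_span_
        return X

    def decision_function(self, X) -> np.ndarray:
        return self._svc.decision_function(self._prepare(X))

    def predict(self, X) -> np.ndarray:
        # sign of the decision value, with the 0 tie going to +1
        return np.where(self.decision_function(X) >= 0, 1, -1)

    def predict_one(self, x: FeatureVector | np.ndarray, id: str = "query") -> Prediction:
        if isinstance(x, FeatureVector):
            if self.schema is not None and x.schema.entries != self.schema.entries:
                raise SchemaError(
                    f"query schema {x.schema.scheme!r} (len {len(x.schema)}) does "
                    f"not match model schema {self.schema.scheme!r} "
                    f"(len {len(self.schema)})"
                )
            x = x.values
        value = float(self.decision_function([x])[0])
        return Prediction(id=id, decision_value=value, label=1 if value >= 0 else -1)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "C": self.C,
            "gamma": self.gamma,
            "scale": self.scale,
            "intercept": self.intercept_,
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "support": self.support_.tolist(),
            "n_train": int(self.alpha_signed_.shape[0]),
            "n_features": self.n_features_in_,
            "scale_offset": None if self.scale_offset_ is None else self.scale_offset_.tolist(),
            "scale_span": None if self.scale_span_ is None else self.scale_span_.tolist(),
            "schema": None if self.schema is None else {
                "scheme": self.schema.scheme,
                "lg": self.schema.lg,
                "entries": [list(e) for e in self.schema.entries],
            },
        }
        return json.dumps(payload)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "RbfSvmClassifier":
        payload = json.loads(text)
        schema = None
        if payload.get("schema"):
            schema = DescriptorSchema(
                scheme=payload["schema"]["scheme"],
                entries=tuple(tuple(e) for e in payload["schema"]["entries"]),
                lg=payload["schema"]["lg"],
            )
        model = cls(C=payload["C"], gamma=payload["gamma"], scale=payload["scale"],
                    schema=schema)
        sv = np.array(payload["support_vectors"], dtype=float)
        dual = np.array(payload["dual_coef"], dtype=float)
        model._svc = _KernelExpansion(sv, dual, payload["intercept"], model.gamma)
        model.support_vectors_ = sv
        model.dual_coef_ = dual
        model.intercept_ = float(payload["intercept"])
        model.n_features_in_ = int(payload["n_features"])
        model.classes_ = np.array([-1, 1])
        model.scale_offset_ = (
            None if payload["scale_offset"] is None else np.array(payload["scale_offset"])
        )
        model.scale_span_ = (
            None if payload["scale_span"] is None else np.array(payload["scale_span"])
        )
        # restore the dual weights aligned with the original training rows,
        # so discriminant analysis on the training table stays valid
        model.support_ = np.array(payload["support"], dtype=int)
        model.alpha_signed_ = np.zeros(int(payload["n_train"]))
        model.alpha_signed_[model.support_] = dual
        return model

    @classmethod
    def load(cls, path) -> "RbfSvmClassifier":
        return cls.from_json(Path(path).read_text())


class _KernelExpansion:
    """Evaluates f(x) = sum_i (alpha_i y_i) K(s_i, x) + b for a loaded model."""

    def __init__(self, sv: np.ndarray, dual: np.ndarray, bias: float, gamma: float):
        self.sv, self.dual, self.bias, self.gamma = sv, dual, bias, gamma

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.sv[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2) @ self.dual + self.bias


# ---------------------------------------------------------------------------
# module-level wrappers
# ---------------------------------------------------------------------------

def train(data: LabeledDataset, C: float, gamma: float, scale: bool = False) -> RbfSvmClassifier:
    """Fit an RBF SVM at fixed (C, gamma) on a labeled dataset."""
    model = RbfSvmClassifier(C=C, gamma=gamma, scale=scale, schema=data.schema)
    return model.fit(data.features, data.labels)


def predict(model: RbfSvmClassifier, x: FeatureVector, id: str = "query") -> Prediction:
    return model.predict_one(x, id=id)


def grid_search(
    data: LabeledDataset,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
    scale: bool = False,
) -> tuple[float, float, pd.DataFrame]:
    """Stratified k-fold grid search over (C, gamma) maximizing CV accuracy.

    Fold assignment is deterministic in ``seed``. Ties break toward the
    smaller C, then the smaller gamma. Returns the winning pair plus the full
    cross-validation table (columns C, gamma, cv_accuracy).
    """
    if folds < 2:
        raise TrainingError(f"folds must be >= 2, got {folds}")
    if not len(C_grid) or not len(gamma_grid):
        raise TrainingError("hyperparameter grids must be non-empty")
    counts = {c: int((data.labels == c).sum()) for c in (-1, 1)}
    if min(counts.values()) < folds:
        raise TrainingError(
            f"each class needs at least {folds} members for {folds}-fold CV; "
            f"class counts: {counts}"
        )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(data.features, data.labels))

    rows = []
    best = (-np.inf, None, None)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            correct = 0
            for train_idx, test_idx in splits:
                model = RbfSvmClassifier(C=C, gamma=gamma, scale=scale)
                model.fit(data.features[train_idx], data.labels[train_idx])
                correct += int((model.predict(data.features[test_idx])
                                == data.labels[test_idx]).sum())
            acc = correct / data.n_samples
            rows.append({"C": C, "gamma": gamma, "cv_accuracy": acc})
            if acc > best[0]:
                best = (acc, C, gamma)
    return best[1], best[2], pd.DataFrame(rows)
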