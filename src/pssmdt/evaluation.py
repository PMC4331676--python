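"""Evaluation protocols and metrics for the DNA-binding classifier.

Metrics follow the standard confusion-matrix definitions:

    SN  = TP / (TP + FN)                       (sensitivity / recall)
    SP  = TN / (TN + FP)                       (specificity)
    ACC = (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP·TN − FP·FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

MCC is defined as 0 when its denominator vanishes, which keeps the
"random predictions score about 0" statement true on degenerate draws.
ROC curves are built by sweeping the decision threshold over the pooled
decision values; AUC equals the Mann–Whitney statistic with ties credited
0.5 (identical to the trapezoidal area under the swept curve).

Protocols
---------
``jackknife``       leave-one-out: each sample is held out exactly once and
                    predicted by a model trained on the rest, at (C, gamma)
                    fixed beforehand; pooled decision values give one
                    report, including the ROC.
``independent_test`` single train on one set, predict another.
``lg_sweep``        re-encode at each maximum lag LG, grid-search (C, gamma)
                    per LG, and report k-fold CV ACC and MCC — the curve
                    used to pick the LG = 5 operating point.

The jackknife reuses a single (C, gamma) chosen once on the full set; this
is the conventional sequencing for this classifier but is optimistically
biased (the tuning saw every sample). Per-fold re-tuning is available by
calling :func:`~pssmdt.svm_engine.grid_search` inside a custom loop.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .datasets import LabeledDataset
from .dt_encoders import DistanceTransformEncoder
from .profile_io import PssmProfile
from .schema import SchemaError
from .svm_engine import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    RbfSvmClassifier,
    TrainingError,
    grid_search,
)


class EvaluationError(ValueError):
    """Invalid evaluation input."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == -1) & (y_pred == 1)).sum()),
            tn=int(((y_true == -1) & (y_pred == -1)).sum()),
            fn=int(((y_true == 1) & (y_pred == -1)).sum()),
        )


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """Exact (SN, SP, ACC, MCC) from confusion counts.

    SN (resp. SP) is 0 when no positives (resp. negatives) were evaluated;
    MCC is 0 when its denominator is 0.
    """
    if counts.total == 0:
        raise EvaluationError("cannot compute metrics from all-zero counts")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = math.sqrt((tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return sn, sp, acc, mcc


def roc_auc(
    decision_values: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) from threshold sweeping, and Mann–Whitney AUC."""
    decision_values = np.asarray(decision_values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(np.unique(labels))) < 2:
        raise EvaluationError("ROC requires both classes among the labels")
    fpr, tpr, _ = roc_curve(labels, decision_values, pos_label=1)
    auc = float(roc_auc_score(labels, decision_values))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


@dataclass
class EvaluationReport:
    """Confusion counts, SN/SP/ACC/MCC, ROC curve and AUC for one protocol run."""

    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float
    roc_points: list[tuple[float, float]]
    auc: float
    protocol: str
    seed: int | None = None
    ids: list[str] = field(default_factory=list)
    decision_values: list[float] = field(default_factory=list)
    predicted_labels: list[int] = field(default_factory=list)

    @classmethod
    def from_predictions(
        cls, ids, y_true, decision_values, protocol: str, seed: int | None = None
    ) -> "EvaluationReport":
        decision_values = np.asarray(decision_values, dtype=float)
        y_pred = np.where(decision_values >= 0, 1, -1)
        counts = ConfusionCounts.from_predictions(y_true, y_pred)
        sn, sp, acc, mcc = compute_metrics(counts)
        points, auc = roc_auc(decision_values, y_true)
        return cls(
            counts=counts, sn=sn, sp=sp, acc=acc, mcc=mcc,
            roc_points=points, auc=auc, protocol=protocol, seed=seed,
            ids=list(ids), decision_values=decision_values.tolist(),
            predicted_labels=y_pred.tolist(),
        )

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "seed": self.seed,
            "counts": {"TP": self.counts.tp, "FP": self.counts.fp,
                       "TN": self.counts.tn, "FN": self.counts.fn},
            "SN_pct": round(100 * self.sn, 2),
            "SP_pct": round(100 * self.sp, 2),
            "ACC_pct": round(100 * self.acc, 2),
            "MCC": round(self.mcc, 4),
            "AUC": round(self.auc, 4),
            "roc_points": self.roc_points,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def summary(self) -> str:
        c = self.counts
        return (
            f"protocol={self.protocol} n={c.total} "
            f"TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn} | "
            f"SN={100 * self.sn:.2f}% SP={100 * self.sp:.2f}% "
            f"ACC={100 * self.acc:.2f}% MCC={self.mcc:.4f} AUC={self.auc:.4f}"
        )

    def roc_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.roc_points, columns=["FPR", "TPR"])


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def jackknife(
    data: LabeledDataset, C: float, gamma: float, scale: bool = False,
    seed: int | None = None,
) -> EvaluationReport:
    """Leave-one-out evaluation at fixed (C, gamma).

    Each sample is held out exactly once; the pooled held-out decision
    values feed the metrics and the ROC curve.
    """
    n = data.n_samples
    if n < 3:
        raise EvaluationError(f"jackknife needs at least 3 samples, got {n}")
    for c in (-1, 1):
        if (data.labels == c).sum() < 2:
            raise EvaluationError(
                "jackknife needs at least 2 members per class so every "
                "training fold keeps both classes"
            )
    values = np.empty(n)
    for i in range(n):
        rest = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        model = RbfSvmClassifier(C=C, gamma=gamma, scale=scale)
        model.fit(data.features[rest], data.labels[rest])
        values[i] = model.decision_function(data.features[i : i + 1])[0]
    return EvaluationReport.from_predictions(
        data.ids, data.labels, values, protocol="jackknife", seed=seed
    )


def independent_test(
    train: LabeledDataset, test: LabeledDataset, C: float, gamma: float,
    scale: bool = False, seed: int | None = None,
) -> EvaluationReport:
    """Train once on ``train``, report performance on ``test``."""
    if train.schema.entries != test.schema.entries:
        raise SchemaError(
            f"train schema {train.schema.scheme!r} (len {len(train.schema)}) "
            f"does not match test schema {test.schema.scheme!r} "
            f"(len {len(test.schema)})"
        )
    if test.n_samples == 0:
        raise EvaluationError("independent test set is empty")
    overlap = set(train.ids) & set(test.ids)
    if overlap:
        warnings.warn(
            f"{len(overlap)} id(s) appear in both train and test sets "
            f"(e.g. {sorted(overlap)[:3]}); results may be homology-biased",
            stacklevel=2,
        )
    model = RbfSvmClassifier(C=C, gamma=gamma, scale=scale)
    model.fit(train.features, train.labels)
    values = model.decision_function(test.features)
    return EvaluationReport.from_predictions(
        test.ids, test.labels, values, protocol="independent", seed=seed
    )


def kfold_report(
    data: LabeledDataset, C: float, gamma: float, folds: int = 5, seed: int = 0,
    scale: bool = False,
) -> EvaluationReport:
    """Stratified k-fold evaluation at fixed (C, gamma), pooled over folds."""
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    values = np.empty(data.n_samples)
    for train_idx, test_idx in skf.split(data.features, data.labels):
        model = RbfSvmClassifier(C=C, gamma=gamma, scale=scale)
        model.fit(data.features[train_idx], data.labels[train_idx])
        values[test_idx] = model.decision_function(data.features[test_idx])
    return EvaluationReport.from_predictions(
        data.ids, data.labels, values, protocol="kfold", seed=seed
    )


def lg_sweep(
    profiles: Sequence[PssmProfile],
    labels: Sequence[int],
    lg_values: Sequence[int],
    folds: int = 5,
    seed: int = 0,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    scale: bool = False,
) -> pd.DataFrame:
    """CV performance of the concatenated DT encoding across maximum lags.

    For each LG, profiles are re-encoded, (C, gamma) re-tuned by grid search
    (dimensionality changes with LG, so reusing one tuning would be
    ill-defined), and stratified k-fold ACC and MCC reported. Returns a
    table with one row per LG.
    """
    labels = np.asarray(labels, dtype=int)
    min_len = min(p.length for p in profiles)
    if min_len <= max(lg_values):
        raise EvaluationError(
            f"all profile lengths (min {min_len}) must exceed the largest "
            f"requested LG ({max(lg_values)})"
        )
    rows = []
    for lg in lg_values:
        encoder = DistanceTransformEncoder(scheme="dt", lg=lg).fit()
        data = LabeledDataset(
            ids=[p.sequence.id for p in profiles],
            features=encoder.transform(profiles),
            labels=labels,
            schema=encoder.schema_,
        )
        C, gamma, _ = grid_search(
            data, C_grid=C_grid, gamma_grid=gamma_grid, folds=folds, seed=seed,
            scale=scale,
        )
        report = kfold_report(data, C=C, gamma=gamma, folds=folds, seed=seed, scale=scale)
        rows.append({"LG": lg, "ACC": report.acc, "MCC": report.mcc,
                     "C": C, "gamma": gamma})
    return pd.DataFrame(rows)


def plot_roc(report: EvaluationReport, path) -> None:
    """Write a ROC curve PNG (optional convenience; requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.roc_table()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(df["FPR"], df["TPR"], label=f"AUC = {report.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("False positive rate (1 - SP)")
    ax.set_ylabel("True positive rate (SN)")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
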