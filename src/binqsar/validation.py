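"""Confusion-matrix metrics and leave-one-out cross-validation.

Metrics follow the usual QSAR reporting conventions: overall accuracy A,
sensitivity A1 (accuracy on actives), specificity A0 (accuracy on
inactives), positive/negative predictive power PPP/NPP, and the Matthews
correlation coefficient.  LOO analogues of the accuracies are reported as
XA / XA0 / XA1.  Percentages are kept at full precision internally and
rounded half-up to one decimal only at the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bqsar import BQSARModel, BQSARParams, fit_binary_qsar


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricSet:
    """Percent accuracies and MCC; undefined ratios are NaN, MCC 0."""

    A: float
    A0: float
    A1: float
    PPP: float
    NPP: float
    MCC: float

    def rounded(self) -> dict[str, float]:
        """Reporting convention: percentages to one decimal, half-up."""
        def r1(v: float) -> float:
            return float("nan") if math.isnan(v) else math.floor(v * 10 + 0.5) / 10

        return {
            "A": r1(self.A),
            "A0": r1(self.A0),
            "A1": r1(self.A1),
            "PPP": r1(self.PPP),
            "NPP": r1(self.NPP),
            "MCC": round(self.MCC, 3),
        }


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Confusion counts with active (1) as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/truth lengths differ")
    if y_true.size == 0:
        raise ValueError("empty input")
    return ConfusionMatrix(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den else float("nan")


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """A, A0, A1, PPP, NPP (percent) and MCC from a confusion matrix.

    MCC is 0 by convention when any of its denominator factors is 0
    (e.g. an all-one-class prediction during permutation tests).
    """
    denom = (
        (cm.TP + cm.FP) * (cm.TP + cm.FN) * (cm.TN + cm.FP) * (cm.TN + cm.FN)
    )
    mcc = 0.0 if denom == 0 else (cm.TP * cm.TN - cm.FP * cm.FN) / math.sqrt(denom)
    return MetricSet(
        A=_ratio(cm.TP + cm.TN, cm.total),
        A0=_ratio(cm.TN, cm.TN + cm.FP),
        A1=_ratio(cm.TP, cm.TP + cm.FN),
        PPP=_ratio(cm.TP, cm.TP + cm.FP),
        NPP=_ratio(cm.TN, cm.TN + cm.FN),
        MCC=mcc,
    )


@dataclass
class ValidationReport:
    """Training, LOO and optional external-test metrics of one model."""

    training: MetricSet
    loo: MetricSet | None = None
    test: MetricSet | None = None
    probabilities: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {"training": self.training.rounded()}
        if self.loo is not None:
            r = self.loo.rounded()
            out["loo"] = {"XA": r["A"], "XA0": r["A0"], "XA1": r["A1"], "MCC": r["MCC"]}
        if self.test is not None:
            out["test"] = self.test.rounded()
        if self.probabilities:
            out["probabilities"] = self.probabilities
        return out


def loo_cv(
    X: np.ndarray,
    y: Sequence[int],
    params: BQSARParams | None = None,
) -> ValidationReport:
    """Leave-one-out cross-validation with a full refit per fold.

    Every fold must retain both classes (each class needs >= 2 members);
    LOO accuracies come from the pooled LOO confusion matrix, training
    metrics from a single fit on all compounds.
    """
    params = params or BQSARParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 compounds for LOO")
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("each class needs >= 2 members so every fold keeps both")

    full = fit_binary_qsar(X, y, params)
    p_train = np.atleast_1d(full.predict_probability(X))
    train_pred = (p_train >= params.decision_threshold).astype(int)

    loo_pred = np.empty(n, dtype=int)
    loo_prob = np.empty(n, dtype=float)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        # folds of an n = 4 dataset contain only 3 compounds
        model = fit_binary_qsar(X[mask], y[mask], params, min_n=3)
        p = model.predict_probability(X[i, : ])
        loo_prob[i] = p
        loo_pred[i] = int(p >= params.decision_threshold)
        mask[i] = True

    return ValidationReport(
        training=compute_metrics(confusion(y, train_pred)),
        loo=compute_metrics(confusion(y, loo_pred)),
        probabilities={
            "training": p_train.tolist(),
            "loo": loo_prob.tolist(),
        },
    )


def evaluate_split(
    split,
    X: np.ndarray,
    y: Sequence[int],
    params: BQSARParams | None = None,
    run_loo: bool = True,
) -> ValidationReport:
    """Fit on the training partition, report training/LOO/test metrics."""
    import warnings as _warnings

    params = params or BQSARParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    tr, te = list(split.train), list(split.test)
    if not te:
        raise ValueError("empty test set")
    if set(tr) & set(te):
        raise ValueError("split partitions overlap")
    if tr == te:
        _warnings.warn("train and test partitions are identical")

    if run_loo:
        report = loo_cv(X[tr], y[tr], params)
    else:
        model = fit_binary_qsar(X[tr], y[tr], params)
        p = np.atleast_1d(model.predict_probability(X[tr]))
        pred = (p >= params.decision_threshold).astype(int)
        report = ValidationReport(training=compute_metrics(confusion(y[tr], pred)))

    model = fit_binary_qsar(X[tr], y[tr], params)
    p_test = np.atleast_1d(model.predict_probability(X[te]))
    test_pred = (p_test >= params.decision_threshold).astype(int)
    report.test = compute_metrics(confusion(y[te], test_pred))
    report.probabilities["test"] = p_test.tolist()
    return report


def aggregate_reports(reports: Sequence[ValidationReport]) -> dict:
    """Mean and SD of every metric over repeated splits (NaNs ignored)."""
    if not reports:
        raise ValueError("no reports to aggregate")
    sections = {"training": "training", "loo": "loo", "test": "test"}
    out: dict = {"n_splits": len(reports)}
    for attr in sections:
        sets = [getattr(r, attr) for r in reports if getattr(r, attr) is not None]
        if not sets:
            continue
        agg = {}
        for name in ("A", "A0", "A1", "PPP", "NPP", "MCC"):
            vals = np.array([getattr(s, name) for s in sets], dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size:
                agg[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0}
        out[attr] = agg
    return out
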