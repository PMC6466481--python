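"""Diagnostic metrics and the feature-selection comparison harness.

Metrics follow the standard dichotomous-test definitions: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/N, and the Youden
index sensitivity + specificity - 1. Cross-validated evaluations pool
out-of-fold confusion counts across folds (micro pooling), so the
reported accuracy is exactly (tp + tn) / n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CASE_LABEL, FeatureTable, stratified_kfold
from .engine import run_wrhfs
from .filters import FILTER_MODELS, score
from .wrapper import ClassifierConfig, prefix_accuracy_curve, tune_and_score


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled confusion counts; positives are the case class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sick(self) -> int:
        return self.tp + self.fn

    @property
    def well(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.sick + self.well


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity/specificity/accuracy as proportions, plus Youden index."""

    sensitivity: float
    specificity: float
    accuracy: float
    youden: float
    counts: ConfusionCounts
    method: str = ""
    n_features: int = 0

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "n_features": self.n_features,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "sensitivity_pct": round(100 * self.sensitivity, 1),
            "specificity_pct": round(100 * self.specificity, 1),
            "accuracy_pct": round(100 * self.accuracy, 1),
            "youden": round(self.youden, 2),
        }


def metrics(counts: ConfusionCounts, method: str = "", n_features: int = 0) -> MetricsReport:
    """Compute the four diagnostic metrics from confusion counts."""
    if counts.sick == 0:
        raise ValueError("no sick individuals: sensitivity is undefined")
    if counts.well == 0:
        raise ValueError("no well individuals: specificity is undefined")
    sens = counts.tp / counts.sick
    spec = counts.tn / counts.well
    acc = (counts.tp + counts.tn) / counts.total
    return MetricsReport(sens, spec, acc, sens + spec - 1, counts, method, n_features)


def evaluate_selection(
    table: FeatureTable,
    selected: Sequence[str],
    config: ClassifierConfig = ClassifierConfig(),
    method: str = "",
) -> MetricsReport:
    """Pooled out-of-fold metrics of the tuned classifier on a feature subset.

    (C, q) are tuned by grid search on mean CV accuracy over the subset;
    the tuned classifier is then refit per fold and out-of-fold predictions
    are pooled into a single confusion table.
    """
    selected = list(selected)
    _, (C, q) = tune_and_score(table, selected, config)
    idx = [table.feature_names.index(f) for f in selected]
    X, y = table.values[:, idx], table.labels
    folds = stratified_kfold(y, config.cv_folds, config.seed)
    pred = np.empty_like(y)
    for f in range(config.cv_folds):
        test = folds == f
        est = config.build(C, q)
        est.fit(X[~test], y[~test])
        pred[test] = est.predict(X[test])
    pos = y == CASE_LABEL
    counts = ConfusionCounts(
        tp=int(np.sum(pos & (pred == CASE_LABEL))),
        fp=int(np.sum(~pos & (pred == CASE_LABEL))),
        tn=int(np.sum(~pos & (pred != CASE_LABEL))),
        fn=int(np.sum(pos & (pred != CASE_LABEL))),
    )
    return metrics(counts, method=method, n_features=len(selected))


def compare_methods(
    table: FeatureTable,
    methods: Sequence[str] = ("wrhfs", "infogain", "relief", "std"),
    config: ClassifierConfig = ClassifierConfig(),
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Head-to-head comparison of WRHFS against single-filter baselines.

    Each baseline filter ranks the features, its prefix-accuracy curve is
    computed, and the prefix size with the best CV accuracy (smallest on
    ties) becomes that method's feature count. WRHFS selects by the
    >threshold cumulative-share rule. Every method is then evaluated via
    :func:`evaluate_selection` and reported as one row (method,
    n_features, counts, sensitivity, specificity, accuracy, Youden).
    """
    if len(methods) < 2:
        raise ValueError("need at least 2 methods to compare")
    rows = []
    for m in methods:
        if m == "wrhfs":
            result = run_wrhfs(table, config=config, threshold=threshold)
            selected = result.weighting.selected
        elif m in FILTER_MODELS:
            sv = score(table, m)
            curve = prefix_accuracy_curve(table, sv, config)
            best = int(np.argmax(curve.prefix_accuracy))  # first max: smallest prefix
            selected = curve.ordered_features[: best + 1]
        else:
            raise ValueError(f"unknown method {m!r}")
        rows.append(evaluate_selection(table, selected, config, method=m).as_row())
    return pd.DataFrame(rows)
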