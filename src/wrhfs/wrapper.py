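"""Prefix-accuracy curves and accuracy-contribution vectors.

A filter ranking is converted into a curve of cross-validated accuracies:
for each prefix length i the top-i ranked features are handed to a
grid-tuned classifier (RBF-SVM by default) and the best mean CV accuracy
is recorded, together with the winning penalty C and kernel bandwidth q.
The per-feature accuracy contribution is the first difference of that
curve; its min-max normalization c (with the first-ranked feature assigned
c = 1.00 by convention) is the quantity the voting stage aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data import FeatureTable, minmax_normalize, stratified_kfold
from .filters import FilterScoreVector

#: default hyperparameter grids (the value sets of a published tuning run)
DEFAULT_PENALTY_GRID = (1, 2, 4, 8, 16, 32, 64, 128, 256)
DEFAULT_BANDWIDTH_GRID = (0.1, 0.2, 0.3, 0.5, 1, 2, 4, 8)


def _make_rbf_svm(C: float, q: float) -> BaseEstimator:
    return SVC(kernel="rbf", C=C, gamma=q)


def _make_gaussian_nb(C: float, q: float) -> BaseEstimator:
    from sklearn.naive_bayes import GaussianNB

    return GaussianNB()


def _make_cart(C: float, q: float) -> BaseEstimator:
    from sklearn.tree import DecisionTreeClassifier

    return DecisionTreeClassifier(random_state=0)


#: classifier plug-in registry: id -> factory(C, q) -> estimator
CLASSIFIER_REGISTRY: dict[str, Callable[[float, float], BaseEstimator]] = {
    "rbf-svm": _make_rbf_svm,
    "gaussian-nb": _make_gaussian_nb,
    "cart": _make_cart,
}


@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier, hyperparameter grids, and CV settings for the wrapper."""

    kind: str = "rbf-svm"
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID
    bandwidth_grid: tuple[float, ...] = DEFAULT_BANDWIDTH_GRID
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_REGISTRY:
            raise ValueError(
                f"unknown classifier {self.kind!r}; registered: {sorted(CLASSIFIER_REGISTRY)}"
            )
        if not self.penalty_grid or not self.bandwidth_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")

    def build(self, C: float, q: float) -> BaseEstimator:
        # standardization is fit inside each training fold only
        return make_pipeline(StandardScaler(), CLASSIFIER_REGISTRY[self.kind](C, q))


@dataclass
class ContributionCurve:
    """Prefix accuracies and accuracy contributions for one filter ranking.

    ``prefix_accuracy[i]`` is the tuned CV accuracy (percent) of the top
    ``i+1`` ranked features. ``raw_contribution`` and ``c`` are reported in
    canonical feature order; the first-ranked feature's raw contribution is
    NaN (undefined) and its normalized contribution is assigned 1.0.
    """

    model_id: str
    ordered_features: list[str]
    prefix_accuracy: np.ndarray
    tuned_params: list[tuple[float, float]]
    feature_names: list[str] = field(default_factory=list)
    raw_contribution: np.ndarray = field(default=None)  # canonical order, NaN for rank 1
    c: np.ndarray = field(default=None)  # canonical order, in [0, 1]


def _cv_accuracy(
    table: FeatureTable, idx: list[int], est_factory, folds: np.ndarray, k: int
) -> float:
    X, y = table.values[:, idx], table.labels
    correct = 0
    for f in range(k):
        test = folds == f
        est = est_factory()
        est.fit(X[~test], y[~test])
        correct += int(np.sum(est.predict(X[test]) == y[test]))
    return 100.0 * correct / len(y)


def tune_and_score(
    table: FeatureTable,
    feature_subset: Sequence[str],
    config: ClassifierConfig = ClassifierConfig(),
    folds: np.ndarray | None = None,
) -> tuple[float, tuple[float, float]]:
    """Grid-search (C, q) on mean CV accuracy over a feature subset.

    Returns (best accuracy in percent at full precision, best (C, q)).
    Ties prefer the smaller penalty, then the smaller bandwidth. The fold
    assignment is stratified and fixed by ``config.seed`` so every grid
    point sees identical folds.
    """
    if not feature_subset:
        raise ValueError("feature subset must be non-empty")
    names = table.feature_names
    for f in feature_subset:
        if f not in names:
            raise ValueError(f"unknown feature {f!r}")
    idx = [names.index(f) for f in feature_subset]
    if folds is None:
        folds = stratified_kfold(table.labels, config.cv_folds, config.seed)
    best_acc, best_params = -1.0, None
    for C in sorted(config.penalty_grid):
        for q in sorted(config.bandwidth_grid):
            acc = _cv_accuracy(
                table, idx, lambda: config.build(C, q), folds, config.cv_folds
            )
            if acc > best_acc:  # strict: ties keep the smaller (C, q)
                best_acc, best_params = acc, (C, q)
    return best_acc, best_params


def prefix_accuracy_curve(
    table: FeatureTable,
    ranking: Sequence[str] | FilterScoreVector,
    config: ClassifierConfig = ClassifierConfig(),
    model_id: str | None = None,
) -> ContributionCurve:
    """Evaluate tuned CV accuracy on every prefix of a feature ranking.

    The ranking is consumed in descending filter-score order; prefix i uses
    the top-i features. (C, q) are re-tuned independently for every prefix.
    The curve need not be monotone. Contributions are filled in via
    :func:`contributions_from_curve`.
    """
    if isinstance(ranking, FilterScoreVector):
        model_id = model_id or ranking.model_id
        ranking = ranking.ranking
    ranking = list(ranking)
    if set(ranking) != set(table.feature_names):
        raise ValueError("ranking must cover the feature universe exactly")
    folds = stratified_kfold(table.labels, config.cv_folds, config.seed)
    accs, params = [], []
    for i in range(1, len(ranking) + 1):
        acc, best = tune_and_score(table, ranking[:i], config, folds=folds)
        accs.append(acc)
        params.append(best)
    curve = ContributionCurve(
        model_id=model_id or "custom",
        ordered_features=ranking,
        prefix_accuracy=np.array(accs),
        tuned_params=params,
        feature_names=table.feature_names,
    )
    curve.raw_contribution, curve.c = contributions_from_curve(curve)
    return curve


def contributions_from_curve(curve: ContributionCurve) -> tuple[np.ndarray, np.ndarray]:
    """First-difference the accuracy curve and min-max normalize.

    raw[i] = accuracy(prefix i) - accuracy(prefix i-1) for ranks i >= 2;
    the first-ranked feature's raw contribution is undefined (NaN).
    Normalization min-maxes the defined raws onto [0, 1], then assigns the
    first-ranked feature c = 1.0 by convention. Both vectors are returned
    re-expressed in canonical feature order.
    """
    acc = curve.prefix_accuracy
    order = curve.ordered_features
    names = curve.feature_names or order
    raw_by_rank = np.concatenate([[np.nan], np.diff(acc)])
    if len(acc) < 2:
        c_by_rank = np.array([1.0])
    else:
        c_by_rank = np.empty_like(raw_by_rank)
        c_by_rank[1:] = minmax_normalize(raw_by_rank[1:])
        c_by_rank[0] = 1.0
    pos = {f: r for r, f in enumerate(order)}
    raw = np.array([raw_by_rank[pos[f]] for f in names])
    c = np.array([c_by_rank[pos[f]] for f in names])
    return raw, c


def per_model_weight(scores: FilterScoreVector, curve: ContributionCurve) -> np.ndarray:
    """Diagnostic per-feature weight: normalized score + normalized contribution.

    This is the text-defined "weight" of a single filter model (s + c, both
    in [0, 1], so at most 2); it is reported per canonical feature order.
    """
    if scores.feature_names != (curve.feature_names or curve.ordered_features):
        raise ValueError("score vector and curve must share the feature universe")
    return scores.s + curve.c
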