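"""The six candidate filter scorers and feature ranking.

Each scorer maps a :class:`~wrhfs.data.FeatureTable` to a
:class:`FilterScoreVector`: raw per-feature scores, min-max-normalized
scores in [0, 1], and a descending ranking (ties broken by canonical
column order).

Scale invariance: ``std`` and ``relief`` operate on features min-max
scaled to the unit interval, so their scores are comparable across
measurement units; ``pearson`` and ``fisher`` are affine-invariant by
construction. Variances are population (1/n) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency

from .data import FeatureTable, minmax_normalize, scale_features

FILTER_MODELS = ("std", "pearson", "fisher", "infogain", "relief", "chi2")

#: bins used to discretize continuous features for infogain / chi2
N_BINS = 10


@dataclass
class FilterScoreVector:
    """One filter model's scores over the canonical feature order."""

    model_id: str
    feature_names: list[str]
    raw_scores: np.ndarray
    s: np.ndarray  # min-max-normalized raw scores
    ranking: list[str]  # features in descending raw-score order

    @classmethod
    def from_raw(
        cls, model_id: str, names: list[str], raw: np.ndarray
    ) -> "FilterScoreVector":
        raw = np.asarray(raw, dtype=float)
        return cls(model_id, list(names), raw, minmax_normalize(raw), _rank(names, raw))


def _rank(names: list[str], raw: np.ndarray) -> list[str]:
    # stable sort on negated scores: ties keep canonical (column) order
    order = np.argsort(-raw, kind="stable")
    return [names[i] for i in order]


def rank_features(scores: FilterScoreVector) -> list[str]:
    """Features in descending raw-score order, ties by canonical order."""
    return _rank(scores.feature_names, scores.raw_scores)


# ---------------------------------------------------------------- scorers


def score_std(table: FeatureTable) -> FilterScoreVector:
    """Population standard deviation of each unit-interval-scaled feature.

    Features are min-max scaled to [0, 1] first, so a balanced binary
    feature scores 0.5 and a constant feature 0; the score reflects spread
    on a common scale rather than raw units.
    """
    scaled = scale_features(table.values)
    raw = scaled.std(axis=0)  # numpy default ddof=0: population SD
    return FilterScoreVector.from_raw("std", table.feature_names, raw)


def score_pearson(table: FeatureTable) -> FilterScoreVector:
    """|Pearson r| between each feature and the {1, 0} label encoding."""
    y = table.binary_labels()
    yc = y - y.mean()
    sy = np.sqrt((yc**2).mean())
    raw = np.zeros(table.n_features)
    for j in range(table.n_features):
        x = table.values[:, j]
        xc = x - x.mean()
        sx = np.sqrt((xc**2).mean())
        if sx == 0 or sy == 0:
            continue
        raw[j] = abs((xc * yc).mean() / (sx * sy))
    return FilterScoreVector.from_raw("pearson", table.feature_names, raw)


def score_fisher(table: FeatureTable) -> FilterScoreVector:
    """Fisher score: between-class mean scatter over within-class variance.

    score = [n1 (mu1 - mu)^2 + n2 (mu2 - mu)^2] / [n1 s1^2 + n2 s2^2]
    with population variances. A zero denominator yields 0 when the
    numerator is also 0; a perfect separator (zero within-class variance,
    distinct means) is capped at 10x the largest finite score so it ranks
    first without propagating infinities.
    """
    y = table.binary_labels().astype(bool)
    raw = np.full(table.n_features, np.nan)
    perfect = []
    for j in range(table.n_features):
        x = table.values[:, j]
        x1, x2 = x[y], x[~y]
        mu = x.mean()
        num = len(x1) * (x1.mean() - mu) ** 2 + len(x2) * (x2.mean() - mu) ** 2
        den = len(x1) * x1.var() + len(x2) * x2.var()
        if den == 0:
            if num == 0:
                raw[j] = 0.0
            else:
                perfect.append(j)
        else:
            raw[j] = num / den
    if perfect:
        finite_max = np.nanmax(raw) if np.isfinite(np.nanmax(raw)) else 1.0
        cap = 10.0 * max(finite_max, 1.0)
        for j in perfect:
            raw[j] = cap
    return FilterScoreVector.from_raw("fisher", table.feature_names, raw)


def _discretize(x: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Equal-frequency binning into at most ``n_bins`` integer codes."""
    distinct = np.unique(x)
    if len(distinct) <= n_bins:
        return np.searchsorted(distinct, x)
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), x, side="right")


def _contingency(codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    cats = np.unique(codes)
    counts = np.zeros((len(cats), 2))
    for i, c in enumerate(cats):
        mask = codes == c
        counts[i, 0] = np.sum(y[mask] == 1)
        counts[i, 1] = np.sum(y[mask] == 0)
    return counts


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def score_infogain(table: FeatureTable) -> FilterScoreVector:
    """Information gain H(Y) - H(Y | X_binned) in bits, clipped at 0.

    Continuous features are discretized by equal-frequency binning into
    ``N_BINS`` bins (fewer when the feature has fewer distinct values).
    """
    y = table.binary_labels()
    hy = _entropy_bits(np.array([y.mean(), 1 - y.mean()]))
    raw = np.zeros(table.n_features)
    n = table.n_samples
    for j in range(table.n_features):
        counts = _contingency(_discretize(table.values[:, j]), y)
        h_cond = 0.0
        for row in counts:
            tot = row.sum()
            if tot:
                h_cond += (tot / n) * _entropy_bits(row / tot)
        raw[j] = max(hy - h_cond, 0.0)
    return FilterScoreVector.from_raw("infogain", table.feature_names, raw)


def score_chi2(table: FeatureTable) -> FilterScoreVector:
    """Pearson chi-square statistic of binned feature x label counts.

    Same discretization as :func:`score_infogain`; no continuity
    correction. A feature independent of the label (proportional table)
    scores 0.
    """
    y = table.binary_labels()
    raw = np.zeros(table.n_features)
    for j in range(table.n_features):
        counts = _contingency(_discretize(table.values[:, j]), y)
        counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            continue
        raw[j] = chi2_contingency(counts, correction=False).statistic
    return FilterScoreVector.from_raw("chi2", table.feature_names, raw)


def score_relief(
    table: FeatureTable, n_iterations: int | None = None, seed: int = 0
) -> FilterScoreVector:
    """Relief weights from nearest same-class and other-class neighbors.

    For each visited instance x the per-feature weight accumulates
    ``diff(x, NearMiss) - diff(x, NearHit)``, where diff is the absolute
    difference on min-max-scaled features and neighbors are nearest by
    Manhattan distance on those scaled features (the instance itself
    excluded). By default every instance is visited exactly once in
    canonical order (a deterministic full sweep); passing ``n_iterations``
    samples instances with replacement under ``seed`` instead, the classic
    randomized variant.
    """
    y = table.binary_labels().astype(bool)
    if min(y.sum(), (~y).sum()) < 2:
        raise ValueError("Relief needs at least 2 samples in each class")
    X = scale_features(table.values)
    n = len(X)
    if n_iterations is None:
        visits = np.arange(n)
    else:
        visits = np.random.default_rng(seed).integers(0, n, size=n_iterations)
    raw = np.zeros(table.n_features)
    for i in visits:
        d = np.abs(X - X[i]).sum(axis=1)
        d[i] = np.inf
        same, other = (y == y[i]), (y != y[i])
        hit = np.where(same & (d == d[same & (d < np.inf)].min()) & (d < np.inf))[0][0]
        miss = np.where(other & (d == d[other].min()))[0][0]
        raw += np.abs(X[i] - X[miss]) - np.abs(X[i] - X[hit])
    raw /= len(visits)
    return FilterScoreVector.from_raw("relief", table.feature_names, raw)


_SCORERS = {
    "std": score_std,
    "pearson": score_pearson,
    "fisher": score_fisher,
    "infogain": score_infogain,
    "relief": score_relief,
    "chi2": score_chi2,
}


def score(table: FeatureTable, model_id: str, **kwargs) -> FilterScoreVector:
    """Dispatch to the scorer named by ``model_id`` (see FILTER_MODELS)."""
    try:
        fn = _SCORERS[model_id]
    except KeyError:
        raise ValueError(f"unknown filter model {model_id!r}") from None
    return fn(table, **kwargs)
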