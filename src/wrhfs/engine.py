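"""The weighting- and ranking-based hybrid feature-selection (WRHFS) core.

Three filter models are fused through four objects, all expressed over the
canonical feature order (p features):

* ``S`` (p x 3): the models' min-max-normalized score vectors;
* ``W`` (p):     the weight-sum vector, row sum of S;
* ``C`` (p x 3): the models' normalized accuracy-contribution vectors;
* ``D`` (p x 3): cumulative contributions — column m at feature f is the
  sum of model m's c over every feature ranked at or above f in model m's
  own ranking.

The effectiveness coefficient of model m is ``P_m = W . D[:, m]``; a
tournament over the candidate filter catalog keeps the three models with
the largest coefficients, and the final feature weight is
``W_r = P x C^T``, i.e. ``W_r[f] = sum_m P_m C[f, m]``. Features are
selected as the minimal descending-weight prefix whose cumulative share of
``sum(W_r)`` strictly exceeds 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FeatureTable, minmax_normalize
from .filters import FILTER_MODELS, FilterScoreVector, score
from .wrapper import ClassifierConfig, ContributionCurve, prefix_accuracy_curve


def aggregate_weight_sum(S: np.ndarray) -> np.ndarray:
    """Weight-sum vector W: elementwise row sum of the score matrix."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[1] != 3:
        raise ValueError("S must be a p x 3 score matrix")
    return S.sum(axis=1)


def build_cumulative_matrix(curves: list[ContributionCurve]) -> np.ndarray:
    """Cumulative-contribution matrix D from three contribution curves.

    Column m holds, for each feature, the cumulative sum of model m's
    normalized contributions taken in model m's own rank order, written
    back in canonical feature order. The top-ranked feature's entry equals
    its own c (1.0 under the first-feature convention); each column is
    non-decreasing along that model's ranking.
    """
    universe = curves[0].feature_names or curves[0].ordered_features
    cols = []
    for curve in curves:
        names = curve.feature_names or curve.ordered_features
        if set(names) != set(universe):
            raise ValueError("curves must share the feature universe")
        pos = {f: i for i, f in enumerate(names)}
        cum, d_by_feature = 0.0, {}
        for f in curve.ordered_features:
            cum += curve.c[pos[f]]
            d_by_feature[f] = cum
        cols.append([d_by_feature[f] for f in universe])
    return np.array(cols).T


def effectiveness(W: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Effectiveness vector P = W x D (one dot product per model column)."""
    W, D = np.asarray(W, dtype=float), np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != W.shape[0]:
        raise ValueError(f"dimension mismatch: W has {W.shape[0]} entries, D is {D.shape}")
    return W @ D


@dataclass
class VotingState:
    """One round's fused state for three active filter models."""

    active_models: list[str]
    scores: list[FilterScoreVector]
    curves: list[ContributionCurve]
    S: np.ndarray  # p x 3 normalized scores
    W: np.ndarray  # length p
    C: np.ndarray  # p x 3 normalized contributions
    D: np.ndarray  # p x 3 cumulative contributions
    P: np.ndarray  # length 3

    @classmethod
    def compute(
        cls,
        model_ids: list[str],
        scores: dict[str, FilterScoreVector],
        curves: dict[str, ContributionCurve],
    ) -> "VotingState":
        sv = [scores[m] for m in model_ids]
        cv = [curves[m] for m in model_ids]
        S = np.column_stack([v.s for v in sv])
        C = np.column_stack([c.c for c in cv])
        W = aggregate_weight_sum(S)
        D = build_cumulative_matrix(cv)
        return cls(list(model_ids), sv, cv, S, W, C, D, effectiveness(W, D))


@dataclass
class FeatureWeighting:
    """Final WRHFS feature weights and the selected subset."""

    feature_names: list[str]
    W_r: np.ndarray
    share: np.ndarray
    cumulative_share: np.ndarray  # in descending-W_r order
    weight01: np.ndarray
    selected: list[str]
    N: int
    threshold: float = 0.5

    def ranked_features(self) -> list[str]:
        order = np.argsort(-self.W_r, kind="stable")
        return [self.feature_names[i] for i in order]


def feature_weights(
    P: np.ndarray,
    C: np.ndarray,
    feature_names: list[str],
    threshold: float = 0.5,
) -> FeatureWeighting:
    """Final weights W_r = P x C^T, shares, and the >threshold selection."""
    P, C = np.asarray(P, dtype=float), np.asarray(C, dtype=float)
    if C.shape != (len(feature_names), len(P)):
        raise ValueError("C must be (n_features x n_models)")
    W_r = C @ P
    total = W_r.sum()
    if total == 0:
        raise ValueError("degenerate vote: all feature weights are zero")
    share = W_r / total
    order = np.argsort(-W_r, kind="stable")
    cumulative = np.cumsum(share[order])
    selected = select_top_features_from_weights(W_r, feature_names, threshold)
    return FeatureWeighting(
        feature_names=list(feature_names),
        W_r=W_r,
        share=share,
        cumulative_share=cumulative,
        weight01=minmax_normalize(W_r),
        selected=selected,
        N=len(selected),
        threshold=threshold,
    )


def select_top_features_from_weights(
    W_r: np.ndarray, feature_names: list[str], threshold: float = 0.5
) -> list[str]:
    """Minimal descending-weight prefix whose cumulative share > threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    W_r = np.asarray(W_r, dtype=float)
    total = W_r.sum()
    if total <= 0:
        raise ValueError("weights must not be all zero")
    order = np.argsort(-W_r, kind="stable")
    cum = np.cumsum(W_r[order]) / total
    n = int(np.argmax(cum > threshold) + 1)
    return [feature_names[i] for i in order[:n]]


def select_top_features(weighting: FeatureWeighting, threshold: float = 0.5) -> list[str]:
    """Re-apply the cumulative-share rule to an existing weighting."""
    return select_top_features_from_weights(
        weighting.W_r, weighting.feature_names, threshold
    )


@dataclass
class TournamentResult:
    """Winning trio and the coefficient history of the filter tournament."""

    winners: list[str]
    coefficients: dict[str, float]  # last recorded coefficient per model
    rounds: list[dict] = field(default_factory=list)


def tournament(
    table: FeatureTable,
    candidate_models: tuple[str, ...] = FILTER_MODELS,
    config: ClassifierConfig = ClassifierConfig(),
    seed: int | None = None,
    _cache: dict | None = None,
) -> TournamentResult:
    """Run the replace-the-worst filter tournament over the candidate set.

    Starts from three models (the first three in catalog order, or a
    seeded random draw when ``seed`` is given), computes the effectiveness
    vector P, records each active model's coefficient, replaces the model
    with the smallest P component by the next unused candidate, and
    repeats until the candidate set is exhausted. Winners are the three
    models with the largest recorded coefficients (ties resolved by
    catalog order). Score vectors and contribution curves are computed
    once per model and cached across rounds.
    """
    candidates = list(candidate_models)
    if len(candidates) < 3:
        raise ValueError("need at least 3 candidate filter models")
    if seed is None:
        active = candidates[:3]
        pool = candidates[3:]
    else:
        rng = np.random.default_rng(seed)
        picks = list(rng.choice(len(candidates), size=3, replace=False))
        active = [candidates[i] for i in picks]
        pool = [m for i, m in enumerate(candidates) if i not in picks]

    cache = _cache if _cache is not None else {}

    def model_state(m: str) -> tuple[FilterScoreVector, ContributionCurve]:
        if m not in cache:
            sv = score(table, m)
            cache[m] = (sv, prefix_accuracy_curve(table, sv, config))
        return cache[m]

    coefficients: dict[str, float] = {}
    rounds = []
    while True:
        scores = {m: model_state(m)[0] for m in active}
        curves = {m: model_state(m)[1] for m in active}
        state = VotingState.compute(active, scores, curves)
        for m, p in zip(active, state.P):
            coefficients[m] = float(p)
        rounds.append({"active": list(active), "P": state.P.tolist()})
        if not pool:
            break
        worst = active[int(np.argmin(state.P))]
        active = [m for m in active if m != worst] + [pool.pop(0)]

    ranked = sorted(
        coefficients, key=lambda m: (-coefficients[m], candidates.index(m))
    )
    return TournamentResult(winners=ranked[:3], coefficients=coefficients, rounds=rounds)


@dataclass
class WRHFSResult:
    """Full pipeline output: winning models, voting state, final weighting."""

    tournament: TournamentResult
    state: VotingState
    weighting: FeatureWeighting


def run_wrhfs(
    table: FeatureTable,
    candidate_models: tuple[str, ...] = FILTER_MODELS,
    config: ClassifierConfig = ClassifierConfig(),
    threshold: float = 0.5,
    seed: int | None = None,
) -> WRHFSResult:
    """End-to-end WRHFS: tournament, final vote with the winners, selection."""
    cache: dict = {}
    result = tournament(table, candidate_models, config, seed=seed, _cache=cache)
    scores = {m: cache[m][0] for m in result.winners}
    curves = {m: cache[m][1] for m in result.winners}
    state = VotingState.compute(result.winners, scores, curves)
    weighting = feature_weights(state.P, state.C, table.feature_names, threshold)
    return WRHFSResult(tournament=result, state=state, weighting=weighting)
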