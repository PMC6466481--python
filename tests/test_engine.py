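import itertools

import numpy as np
import pytest

from wrhfs import (
    ClassifierConfig,
    SyntheticSpec,
    aggregate_weight_sum,
    build_cumulative_matrix,
    effectiveness,
    feature_weights,
    generate_synthetic_cohort,
    run_wrhfs,
    select_top_features,
    tournament,
)
from wrhfs.engine import select_top_features_from_weights
from wrhfs.fixtures import WINNING_MODELS, contribution_matrices, effectiveness_coefficients, model_scores
from tests.test_wrapper import make_curve


class TestAggregateWeightSum:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([0.9123, 1.0000, 0.0001], 1.9124),
            ([0.9884, 0.9582, 0.0788], 2.0254),
            ([0.0, 0.0, 0.0], 0.0),
        ],
    )
    def test_published_rows(self, row, expected):
        assert aggregate_weight_sum(np.array([row]))[0] == pytest.approx(expected)

    def test_fixture_weight_sum_column(self):
        df = model_scores()
        W = aggregate_weight_sum(df[["std", "relief", "infogain"]].to_numpy())
        np.testing.assert_allclose(W, df["weight_sum"], atol=1e-4 + 1e-12)


class TestBuildCumulativeMatrix:
    def test_cumsum_in_rank_order(self):
        c1 = make_curve([50, 60, 55], ["a", "b", "c"])
        from wrhfs import contributions_from_curve

        c1.raw_contribution, c1.c = contributions_from_curve(c1)  # c = (1, 1, 0)
        D = build_cumulative_matrix([c1, c1, c1])
        np.testing.assert_allclose(D[:, 0], [1.0, 2.0, 2.0])

    def test_top_ranked_entry_equals_own_c(self, planted_cohort, fast_config):
        from wrhfs import prefix_accuracy_curve, score

        table, _ = planted_cohort
        curves = [
            prefix_accuracy_curve(table, score(table, m), fast_config)
            for m in ("pearson", "fisher", "infogain")
        ]
        D = build_cumulative_matrix(curves)
        names = table.feature_names
        for k, curve in enumerate(curves):
            top = curve.ordered_features[0]
            assert D[names.index(top), k] == pytest.approx(1.0)
            # each column non-decreasing along its own ranking
            along = [D[names.index(f), k] for f in curve.ordered_features]
            assert np.all(np.diff(along) >= -1e-12)

    def test_published_std_column_rebuilt_from_sd_curve(self):
        """Cumsum of the published SD-model normalized contributions matches
        the published cumulative column within 2-dp input rounding."""
        from wrhfs.fixtures import sd_model_curve

        sd = sd_model_curve()
        curve = make_curve(
            sd["accuracy"].to_numpy(), list(sd["feature"]), names=list(sd["feature"])
        )
        curve.c = sd["contribution01"].to_numpy(dtype=float)
        D = build_cumulative_matrix([curve, curve, curve])
        printed = contribution_matrices().set_index("feature")["d_std"]
        for f, d in zip(sd["feature"], D[:, 0]):
            assert abs(d - printed[f]) <= 0.03, f
        # ties from adjacent zero-c features survive: Height equals α-HBD
        assert printed["Height"] == printed["α-HBD"] == 1.6654


class TestEffectiveness:
    def test_reproduces_published_coefficients(self):
        scores = model_scores()
        W = scores["weight_sum"].to_numpy()
        mats = contribution_matrices().set_index("feature").loc[scores["feature"]]
        P = effectiveness(W, mats[["d_std", "d_relief", "d_infogain"]].to_numpy())
        coeffs = effectiveness_coefficients().set_index("method")["coefficient"]
        np.testing.assert_array_equal(
            np.round(P), [coeffs[m] for m in WINNING_MODELS]
        )

    def test_linearity_and_annihilator(self):
        rng = np.random.default_rng(0)
        W, D = rng.random(6), rng.random((6, 3))
        np.testing.assert_allclose(effectiveness(2 * W, D), 2 * effectiveness(W, D))
        np.testing.assert_allclose(effectiveness(np.zeros(6), D), 0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            effectiveness(np.ones(4), np.ones((5, 3)))


class TestFeatureWeights:
    def test_linear_in_P_and_column_permutation_invariant(self):
        rng = np.random.default_rng(1)
        P, C = np.array([52.0, 61.0, 63.0]), rng.random((8, 3))
        names = [f"f{i}" for i in range(8)]
        w = feature_weights(P, C, names)
        np.testing.assert_allclose(w.W_r, C @ P)
        perm = [2, 0, 1]
        w2 = feature_weights(P[perm], C[:, perm], names)
        np.testing.assert_allclose(w2.W_r, w.W_r)
        np.testing.assert_allclose(w.share.sum(), 1.0)
        assert np.all(np.diff(w.cumulative_share) >= -1e-12)
        assert w.cumulative_share[-1] == pytest.approx(1.0)

    def test_unanimous_top_contributor(self):
        # a feature with c = 1 in every model gets W_r = sum(P)
        P = np.array([52.0, 61.0, 63.0])
        C = np.vstack([[1.0, 1.0, 1.0], np.full((5, 3), 0.1)])
        names = [f"f{i}" for i in range(6)]
        w = feature_weights(P, C, names)
        assert w.W_r[0] == pytest.approx(176.0)

    def test_degenerate_vote_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            feature_weights(np.zeros(3), np.zeros((4, 3)), list("abcd"))


class TestSelectTopFeatures:
    def test_published_weights_select_nine(self):
        from wrhfs.fixtures import final_weights

        df = final_weights()
        sel = select_top_features_from_weights(
            df["weight"].to_numpy(), list(df["feature"])
        )
        assert len(sel) == 9
        assert sel[0] == "Age" and "CK-MB" in sel

    def test_uniform_and_single(self):
        assert len(select_top_features_from_weights(np.ones(4), list("abcd"))) == 3
        names = ["only", "z"]
        assert select_top_features_from_weights(np.array([5.0, 0.0]), names, 0.9) == ["only"]

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="threshold"):
            select_top_features_from_weights(np.ones(3), list("abc"), 1.5)


class TestTournament:
    def test_three_candidates_single_round(self, planted_cohort, fast_config):
        table, _ = planted_cohort
        res = tournament(table, ("pearson", "fisher", "infogain"), fast_config)
        assert sorted(res.winners) == sorted(["pearson", "fisher", "infogain"])
        assert len(res.rounds) == 1

    def test_deterministic_and_stable_for_three_candidates(self, fast_config):
        """Identical catalogs give identical tournaments, and with exactly
        three candidates every catalog permutation returns the same trio.

        With larger catalogs the winning set is NOT order-invariant in
        general: a model's effectiveness coefficient P_m = W . D_m depends
        on which other two models are co-active (their scores enter W), so
        different visit orders can record different coefficients for the
        same model.
        """
        table, _ = generate_synthetic_cohort(
            SyntheticSpec(n_samples=250, n_informative=2, n_noise=3, effect_size=1.5, seed=3)
        )
        cache = {}
        catalog = ("pearson", "fisher", "infogain")
        base = tournament(table, catalog, fast_config, _cache=cache)
        for perm in itertools.permutations(catalog):
            res = tournament(table, perm, fast_config, _cache=cache)
            assert sorted(res.winners) == sorted(base.winners)
        again = tournament(table, catalog, fast_config, _cache=cache)
        assert again.winners == base.winners
        assert again.coefficients == base.coefficients

    def test_too_few_candidates_rejected(self, planted_cohort, fast_config):
        table, _ = planted_cohort
        with pytest.raises(ValueError, match="at least 3"):
            tournament(table, ("pearson", "fisher"), fast_config)


class TestEndToEnd:
    def test_pipeline_selects_planted_features(self, planted_cohort, fast_config):
        table, informative = planted_cohort
        res = run_wrhfs(table, config=fast_config)
        assert set(informative) <= set(res.weighting.selected) or set(
            res.weighting.selected
        ) <= set(informative)
        # selection rule re-applies consistently
        assert select_top_features(res.weighting) == res.weighting.selected

    def test_noise_removal_preserves_relative_order(self, fast_config):
        """Dropping a pure-noise column keeps the relative W_r order of the rest."""
        table, informative = generate_synthetic_cohort(
            SyntheticSpec(n_samples=250, n_informative=2, n_noise=3, effect_size=1.5, seed=6)
        )
        models = ("pearson", "fisher", "infogain")
        full = run_wrhfs(table, candidate_models=models, config=fast_config)
        drop = [n for n in table.feature_names if n != "noise_03"]
        reduced = run_wrhfs(table.subset(drop), candidate_models=models, config=fast_config)
        full_rank = [f for f in full.weighting.ranked_features() if f != "noise_03"]
        assert reduced.weighting.ranked_features() == full_rank
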