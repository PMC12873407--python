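"""Edge ranking, ridge canonical direction, nested CV hygiene, permutation
inference, edge maps, region contributions, subtype contrasts."""

import warnings

import numpy as np
import pandas as pd
import pytest

import funcmap as fm
from funcmap.brainmap import RidgeDirection


class TestRankEdges:
    def test_single_planted_edge_tops_ranking(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed + 100)
            y = rng.standard_normal(200)
            E = rng.standard_normal((200, 501))
            E[:, 0] = 0.8 * y + rng.standard_normal(200)
            order, _ = fm.rank_edges_bootstrap(E, y, reps=100, fraction=0.95, seed=seed)
            hits += order[0] == 0
        assert hits >= 19

    def test_permuted_target_stays_below_null_bound(self):
        rng = np.random.default_rng(9)
        E = rng.standard_normal((200, 500))
        y = rng.standard_normal(200)
        _, scores = fm.rank_edges_bootstrap(E, y, reps=100, fraction=0.95, seed=0)
        assert scores.max() <= 0.35

    def test_seeded_repeat_identical(self):
        rng = np.random.default_rng(1)
        E = rng.standard_normal((50, 30))
        y = rng.standard_normal(50)
        a = fm.rank_edges_bootstrap(E, y, reps=20, seed=7)
        b = fm.rank_edges_bootstrap(E, y, reps=20, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_zero_variance_edge_scores_zero(self):
        rng = np.random.default_rng(2)
        E = rng.standard_normal((60, 5))
        E[:, 3] = 1.0
        _, scores = fm.rank_edges_bootstrap(E, rng.standard_normal(60), reps=10, seed=0)
        assert scores[3] == 0.0


class TestRidgeDirection:
    def test_single_feature_preserves_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((80, 1))
        y = 0.6 * x[:, 0] + rng.standard_normal(80)
        for lam in (0.1, 1.0, 10.0):
            model = fm.fit_rcc(x, y, lam)
            pred = model.score_subjects(x)
            assert abs(np.corrcoef(pred, y)[0, 1]) == pytest.approx(
                abs(np.corrcoef(x[:, 0], y)[0, 1]), abs=1e-10
            )

    def test_infinite_penalty_limit_is_marginal_correlation_weighting(self):
        rng = np.random.default_rng(1)
        E = rng.standard_normal((100, 8))
        y = rng.standard_normal(100)
        model = fm.fit_rcc(E, y, 1e6)
        Z = (E - E.mean(axis=0)) / E.std(axis=0)
        direction = Z.T @ (y - y.mean())
        cos = (model.w @ direction) / (np.linalg.norm(model.w) * np.linalg.norm(direction))
        assert cos == pytest.approx(1.0, abs=1e-4)

    def test_realizable_target_fit_near_perfectly(self):
        rng = np.random.default_rng(2)
        E = rng.standard_normal((100, 2))
        y = 2.0 * E[:, 0] - 1.0 * E[:, 1]
        model = fm.fit_rcc(E, y, 1e-6)
        r = np.corrcoef(model.score_subjects(E), y)[0, 1]
        assert r >= 0.999

    def test_prediction_invariant_to_edge_rescaling(self):
        rng = np.random.default_rng(3)
        E = rng.standard_normal((60, 5))
        y = rng.standard_normal(60)
        scale = np.array([10.0, 0.1, 3.0, 1.0, 7.0])
        a = fm.fit_rcc(E, y, 2.0).score_subjects(E)
        b = fm.fit_rcc(E * scale + 5.0, y, 2.0).score_subjects(E * scale + 5.0)
        assert np.allclose(a, b, atol=1e-8)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            fm.fit_rcc(np.ones((30, 2)), np.ones(30), 0.0)

    def test_primal_and_dual_solutions_agree(self):
        rng = np.random.default_rng(4)
        E = rng.standard_normal((20, 50))  # p > n: dual path
        y = rng.standard_normal(20)
        dual = RidgeDirection(lam=3.0).fit(E, y)
        Z = (E - dual.mean_) / dual.scale_
        primal = np.linalg.solve(Z.T @ Z + 3.0 * np.eye(50), Z.T @ (y - y.mean()))
        assert np.allclose(dual.w, primal, atol=1e-8)


class TestNestedCv:
    def test_planted_signal_predicted_out_of_sample(self, planted_edge_dataset, planted_edge_matrix, cheap_rcc_config):
        E, _, _ = planted_edge_matrix
        y = planted_edge_dataset.true_scores[:, 0]
        res = fm.nested_cv_predict(E, y, cheap_rcc_config)
        assert res.canonical_r >= 0.4

    def test_pure_noise_target_no_leakage(self, planted_edge_matrix, cheap_rcc_config):
        E, _, _ = planted_edge_matrix
        y0 = np.random.default_rng(5).standard_normal(E.shape[0])
        res = fm.nested_cv_predict(E, y0, cheap_rcc_config)
        assert abs(res.canonical_r) <= 0.15

    def test_seeded_repeat_identical(self, cheap_rcc_config):
        rng = np.random.default_rng(0)
        E = rng.standard_normal((60, 100))
        y = E[:, 0] + rng.standard_normal(60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            a = fm.nested_cv_predict(E, y, cheap_rcc_config)
            b = fm.nested_cv_predict(E, y, cheap_rcc_config)
        assert np.array_equal(a.fc_scores, b.fc_scores)
        assert a.canonical_r == b.canonical_r
        assert np.array_equal(a.selected_edges, b.selected_edges)

    def test_hyperparameters_within_search_space(self, planted_edge_matrix, cheap_rcc_config, planted_edge_dataset):
        E, _, _ = planted_edge_matrix
        res = fm.nested_cv_predict(E, planted_edge_dataset.true_scores[:, 0], cheap_rcc_config)
        for _, _, lam, nf, _ in res.chosen_hyperparams:
            assert 1.0 <= lam <= 10.0
            assert 50 <= nf <= 300


class TestPermutationTest:
    def test_planted_signal_significant(self, planted_edge_dataset, planted_edge_matrix, cheap_rcc_config):
        E, _, _ = planted_edge_matrix
        y = planted_edge_dataset.true_scores[:, 0]
        res = fm.nested_cv_predict(E, y, cheap_rcc_config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            p, null_r = fm.permutation_test(E, y, cheap_rcc_config, res.canonical_r, n_permutations=50)
        assert p <= 0.05
        assert 0 < p <= 1
        assert null_r.size == 50

    def test_few_permutations_warns(self, cheap_rcc_config):
        rng = np.random.default_rng(0)
        E = rng.standard_normal((60, 50))
        y = rng.standard_normal(60)
        with pytest.warns(UserWarning, match="permutations"):
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                fm.permutation_test(E, y, cheap_rcc_config, 0.9, n_permutations=3)


class TestEdgeAssociationMap:
    def test_planted_edges_recalled_without_false_positives(self, planted_edge_dataset, planted_edge_matrix):
        E, _, planted = planted_edge_matrix
        ds = planted_edge_dataset
        amap = fm.edge_association_map(E, ds.true_scores[:, 0], ds.covariates, fdr_threshold=0.001)
        sig = set(amap.loc[amap["significant"], "edge"])
        recall = len(sig & planted[1]) / len(planted[1])
        # the other factor's planted edges are genuinely associated through
        # the negative inter-factor correlation, so exclude both sets
        false_pos = sig - planted[1] - planted[2]
        assert recall >= 0.6
        assert len(false_pos) <= 2

    def test_null_data_yields_no_significant_edges(self):
        rng = np.random.default_rng(0)
        amap = fm.edge_association_map(
            rng.standard_normal((100, 500)), rng.standard_normal(100), None, fdr_threshold=0.001
        )
        assert amap["significant"].sum() == 0

    def test_bh_monotonicity(self):
        rng = np.random.default_rng(1)
        amap = fm.edge_association_map(
            rng.standard_normal((50, 100)), rng.standard_normal(50), None
        )
        assert (amap["q"] >= amap["p"] - 1e-15).all()
        assert set(amap.loc[amap["significant"], "edge"]) <= set(
            amap.loc[amap["p"] < 0.001, "edge"]
        )


class TestRegionContributions:
    def _map(self, R=5):
        return fm.edge_index_map(R)

    def test_single_edge_splits_credit(self):
        emap = self._map()
        out = fm.region_contributions([0], [1.0], emap)  # edge 0 = (0, 1)
        props = out.set_index("region")["proportion"]
        assert props[0] == pytest.approx(0.5)
        assert props[1] == pytest.approx(0.5)

    def test_star_hub_takes_half(self):
        emap = self._map()
        # edges (0,1), (0,2), (0,3): region 0 is the hub
        ids = emap.query("i == 0 and j in [1,2,3]")["edge"].tolist()
        out = fm.region_contributions(ids, [1.0] * 3, emap)
        assert out.set_index("region")["proportion"][0] == pytest.approx(0.5)
        assert out.loc[0, "region"] == 0  # ranked first

    def test_proportions_sum_to_one_and_scale_invariant(self):
        emap = self._map()
        rng = np.random.default_rng(0)
        ids = rng.choice(len(emap), 6, replace=False)
        w = rng.standard_normal(6)
        a = fm.region_contributions(ids, w, emap)
        b = fm.region_contributions(ids, 37.0 * w, emap)
        assert a["proportion"].sum() == pytest.approx(1.0)
        assert np.allclose(a["proportion"], b["proportion"])

    def test_empty_edge_set_warns(self):
        with pytest.warns(UserWarning):
            out = fm.region_contributions([], [], self._map())
        assert out.empty

    def test_planted_hub_ranked_first(self):
        emap = self._map(10)
        hub_edges = emap.query("i == 4 or j == 4")["edge"].to_numpy()[:6]
        other = emap.query("i != 4 and j != 4")["edge"].to_numpy()[:3]
        ids = np.concatenate([hub_edges, other])
        out = fm.region_contributions(ids, np.ones(len(ids)), emap)
        assert out.loc[0, "region"] == 4


class TestSubtypeContrasts:
    def test_identical_groups_show_nothing(self):
        rng = np.random.default_rng(0)
        block = rng.standard_normal((40, 30))
        E = np.vstack([block, block])
        labels = np.array(["a"] * 40 + ["b"] * 40)
        res = fm.subtype_contrast_edges(E, labels)
        df = res[("a", "b")]
        assert np.abs(df["t"]).max() <= 1e-10
        assert df["significant"].sum() == 0

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(4)
        E = rng.standard_normal((120, 100))
        E[:60, :10] += 1.0
        labels = np.array(["a"] * 60 + ["b"] * 60)
        df = fm.subtype_contrast_edges(E, labels)[("a", "b")]
        assert df["significant"][:10].sum() >= 8
        assert df["significant"][10:].sum() <= 2

    def test_group_order_flips_t_sign(self):
        rng = np.random.default_rng(5)
        E = rng.standard_normal((60, 20))
        E[:30] += 0.5
        labels = np.array(["a"] * 30 + ["b"] * 30)
        t_ab = fm.subtype_contrast_edges(E, labels)[("a", "b")]["t"].to_numpy()
        t_ba = fm.subtype_contrast_edges(E[::-1], labels[::-1])[("b", "a")]["t"].to_numpy()
        assert np.allclose(t_ab, -t_ba)

    def test_tiny_group_skipped(self):
        rng = np.random.default_rng(6)
        E = rng.standard_normal((41, 10))
        labels = np.array(["a"] * 40 + ["c"])
        res = fm.subtype_contrast_edges(E, labels)
        assert ("a", "c") not in res
        assert ("a", "c") in res["skipped"]
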