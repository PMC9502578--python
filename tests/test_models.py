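import numpy as np
import pytest
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression

import placperm as pp

from conftest import make_table


def random_table(seed, n, p, with_signal=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = 1.0 + X @ beta + rng.normal(0, 0.3, size=n)
    y = y - y.min()  # keep CI nonnegative
    return make_table(X, ci=y)


class TestLinearFit:
    def test_exact_recovery_on_linear_data(self, tiny_linear_table):
        m = pp.fit(tiny_linear_table, ["f0"], pp.ModelSpec(kind="linear"))
        assert m.linear_coef[0] == pytest.approx(2.0, abs=1e-8)
        assert m.linear_intercept == pytest.approx(1.0, abs=1e-8)
        preds = pp.predict(m, tiny_linear_table)
        assert np.allclose(preds, tiny_linear_table.ci, atol=1e-8)

    def test_matches_sklearn_linear_regression(self):
        t = random_table(0, 30, 4)
        m = pp.fit(t, t.feature_names, pp.ModelSpec(kind="linear"))
        sk = LinearRegression().fit(t.values, t.ci)
        assert np.allclose(m.linear_coef, sk.coef_, atol=1e-10)
        assert m.linear_intercept == pytest.approx(sk.intercept_, abs=1e-10)

    def test_singular_design_rejected(self):
        X = np.ones((10, 2))
        X[:, 0] = np.arange(10)
        X[:, 1] = 2 * X[:, 0]  # collinear
        t = make_table(X, ci=np.arange(10, dtype=float))
        with pytest.raises(ValueError, match="singular"):
            pp.fit(t, t.feature_names, pp.ModelSpec(kind="linear"))

    def test_too_many_features_warns_not_errors(self):
        t = random_table(1, 6, 5)
        with pytest.warns(UserWarning, match="cap"):
            pp.fit(t, t.feature_names, pp.ModelSpec(kind="linear"))

    def test_missing_target_rejected(self):
        t = make_table(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="CI"):
            pp.fit(t, t.feature_names, pp.ModelSpec(kind="linear"))


class TestForest:
    def test_bagged_trees_match_sklearn_forest(self):
        """BaggedTrees must be prediction-identical to sklearn's forest with
        all features considered per split (same bootstrap + seeding)."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        Xt = rng.normal(size=(25, 6))
        for seed in (0, 7, 123):
            mine = pp.BaggedTrees(n_trees=40, seed=seed).fit(X, y)
            sk = RandomForestRegressor(
                n_estimators=40, random_state=seed, max_features=None
            ).fit(X, y)
            assert np.array_equal(mine.predict(Xt), sk.predict(Xt))
            assert np.allclose(
                mine.feature_importances_, sk.feature_importances_, atol=1e-12
            )

    def test_single_unbagged_tree_memorizes_training_points(self):
        t = random_table(2, 20, 3)
        spec = pp.ModelSpec(kind="forest", n_trees=1, seed=0, bootstrap=False)
        m = pp.fit(t, t.feature_names, spec)
        assert np.allclose(pp.predict(m, t), t.ci, atol=1e-6)

    def test_forest_deterministic_given_seed(self):
        t = random_table(3, 25, 4)
        spec = pp.ModelSpec(kind="forest", n_trees=20, seed=9)
        p1 = pp.predict(pp.fit(t, t.feature_names, spec), t)
        p2 = pp.predict(pp.fit(t, t.feature_names, spec), t)
        assert np.array_equal(p1, p2)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            pp.ModelSpec(kind="forest")


class TestEnsemble:
    def test_prediction_is_mean_of_components(self):
        t = random_table(4, 30, 5)
        spec = pp.ModelSpec(kind="ensemble", n_trees=20, seed=2)
        ens = pp.fit(t, t.feature_names, spec)
        lin = pp.fit(t, t.feature_names, pp.ModelSpec(kind="linear"))
        forest = pp.fit(t, t.feature_names, pp.ModelSpec(kind="forest", n_trees=20, seed=2))
        combo = 0.5 * pp.predict(lin, t) + 0.5 * pp.predict(forest, t)
        assert np.allclose(pp.predict(ens, t), combo, atol=1e-12)

    def test_stored_linear_component_identical_to_standalone(self):
        t = random_table(5, 30, 5)
        ens = pp.fit(t, t.feature_names, pp.ModelSpec(kind="ensemble", n_trees=10, seed=3))
        lin = pp.fit(t, t.feature_names, pp.ModelSpec(kind="linear"))
        assert np.array_equal(ens.linear_coef, lin.linear_coef)
        assert ens.linear_intercept == lin.linear_intercept

    def test_custom_weights(self):
        t = random_table(6, 20, 3)
        spec = pp.ModelSpec(kind="ensemble", n_trees=10, seed=1, ensemble_weights=(0.3, 0.7))
        m = pp.fit(t, t.feature_names, spec)
        lin = m.linear_intercept + t.values @ m.linear_coef
        forest = m.forest.predict(t.values)
        assert np.allclose(pp.predict(m, t), 0.3 * lin + 0.7 * forest, atol=1e-12)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pp.ModelSpec(kind="ensemble", seed=0, ensemble_weights=(0.6, 0.6))

    def test_feature_mismatch_reported(self):
        t = random_table(7, 15, 3)
        m = pp.fit(t, t.feature_names, pp.ModelSpec(kind="linear"))
        other = make_table(np.zeros((3, 1)), features=["other"])
        with pytest.raises(KeyError, match="f0"):
            pp.predict(m, other)


class TestLoocv:
    def test_perfectly_linear_data_predicted_exactly(self, tiny_linear_table):
        preds = pp.loocv(tiny_linear_table, ["f0"], pp.ModelSpec(kind="linear"))
        assert np.allclose(preds, tiny_linear_table.ci, atol=1e-8)
        assert pp.pearson_r(tiny_linear_table.ci, preds) == pytest.approx(1.0)

    @pytest.mark.parametrize("kind", ["linear", "forest", "ensemble"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6])
    def test_equals_bruteforce_loop_with_sklearn(self, kind, seed):
        """The LOOCV engine must agree elementwise with an explicit fold loop
        built from sklearn estimators (independent of the package's fit path)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 31))
        p = int(rng.integers(2, 5))
        t = random_table(seed + 100, n, p)
        spec = pp.ModelSpec(kind=kind, n_trees=15, seed=seed)
        mine = pp.loocv(t, t.feature_names, spec)
        oracle = np.empty(n)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            X_tr, y_tr, X_te = t.values[mask], t.ci[mask], t.values[i : i + 1]
            parts = []
            if kind in ("linear", "ensemble"):
                parts.append(LinearRegression().fit(X_tr, y_tr).predict(X_te)[0])
            if kind in ("forest", "ensemble"):
                rf = RandomForestRegressor(
                    n_estimators=15, random_state=seed, max_features=None
                ).fit(X_tr, y_tr)
                parts.append(rf.predict(X_te)[0])
            oracle[i] = np.mean(parts)
        assert np.allclose(mine, oracle, atol=1e-10)

    def test_failure_names_left_out_chemical(self):
        X = np.zeros((5, 2))
        X[:, 0] = [1, 1, 1, 1, 2.0]  # constant once the last row is left out
        X[:, 1] = np.arange(5.0)
        t = make_table(X, ci=np.arange(5.0))
        with pytest.raises(RuntimeError, match="c4"):
            pp.loocv(t, t.feature_names, pp.ModelSpec(kind="linear"))

    def test_strict_mode_refits_normalization_per_fold(self):
        t = random_table(8, 12, 2)
        spec = pp.ModelSpec(kind="linear")
        default = pp.loocv(t, t.feature_names, spec)
        strict = pp.loocv(t, t.feature_names, spec, refit_normalization=True)
        # OLS predictions are invariant to affine feature rescaling
        assert np.allclose(default, strict, atol=1e-8)


class TestRankFeatures:
    # rank pairs and overall ranking of the seven descriptors of the
    # published ensemble model (MLFER_BH, AATSC3v, AATSC2i, GATS1s,
    # AATSC1c, MATS2i, GATS5m) used as a frozen oracle
    COEF = np.array([-0.035, -0.039, -0.023, 0.019, 0.045, 0.072, -0.029])
    IMP = np.array([0.133, 0.159, 0.100, 0.180, 0.170, 0.101, 0.157])

    def _mock_ensemble(self, coef, importances):
        class FakeForest:
            feature_importances_ = np.asarray(importances)

        m = pp.FittedModel(
            spec=pp.ModelSpec(kind="ensemble", seed=0),
            feature_names=[f"f{j}" for j in range(len(coef))],
            linear_coef=np.asarray(coef, dtype=float),
            linear_intercept=0.0,
        )
        m.forest = FakeForest()
        return m

    def test_published_rank_pairs_reproduce_overall_ranking(self):
        table = pp.rank_features(self._mock_ensemble(self.COEF, self.IMP))
        assert list(table["rank_linear"]) == [4, 3, 6, 7, 2, 1, 5]
        assert list(table["rank_forest"]) == [5, 3, 7, 1, 2, 6, 4]
        assert list(table["overall_rank"]) == [5, 2, 7, 4, 1, 3, 5]

    def test_rank_sum_logic(self):
        # linear ranks 2,1,3 ; forest ranks 2,1,3 -> sums 4,2,6 -> overall 2,1,3
        table = pp.rank_features(self._mock_ensemble([0.5, 0.9, 0.3], [0.3, 0.4, 0.2]))
        assert list(table["overall_rank"]) == [2, 1, 3]
        # rank pairs (2,2), (1,6), (3,3) -> rank sums 4,7,6 -> overall 1,3,2
        from scipy.stats import rankdata

        sums = np.array([2 + 2, 1 + 6, 3 + 3])
        assert list(rankdata(sums, method="min").astype(int)) == [1, 3, 2]

    def test_tied_rank_sums_share_min_rank(self):
        table = pp.rank_features(self._mock_ensemble([0.9, 0.5], [0.4, 0.6]))
        # ranks (1,2) and (2,1): equal sums -> both overall rank 1
        assert list(table["overall_rank"]) == [1, 1]

    def test_single_feature_all_ranks_one(self):
        table = pp.rank_features(self._mock_ensemble([0.9], [1.0]))
        assert list(table["rank_linear"]) == [1]
        assert list(table["overall_rank"]) == [1]

    def test_non_ensemble_rejected(self):
        t = make_table(np.random.default_rng(0).normal(size=(10, 2)), ci=np.arange(10.0))
        m = pp.fit(t, t.feature_names, pp.ModelSpec(kind="linear"))
        with pytest.raises(ValueError, match="ensemble"):
            pp.rank_features(m)


class TestPersistence:
    def test_linear_roundtrip(self, tmp_path, tiny_linear_table):
        m = pp.fit(tiny_linear_table, ["f0"], pp.ModelSpec(kind="linear"))
        pp.save_model(m, tmp_path / "m.json")
        back = pp.load_model(tmp_path / "m.json")
        assert np.allclose(back.linear_coef, m.linear_coef)
        assert back.linear_intercept == pytest.approx(m.linear_intercept)
        assert np.allclose(
            pp.predict(back, tiny_linear_table), pp.predict(m, tiny_linear_table)
        )

    def test_ensemble_refits_forest_from_training_table(self, tmp_path):
        t = random_table(9, 25, 4)
        spec = pp.ModelSpec(kind="ensemble", n_trees=15, seed=4)
        m = pp.fit(t, t.feature_names, spec)
        pp.save_model(m, tmp_path / "m.json")
        back = pp.load_model(tmp_path / "m.json", training_table=t)
        assert np.array_equal(pp.predict(back, t), pp.predict(m, t))

    def test_wrong_training_table_detected(self, tmp_path):
        t = random_table(10, 25, 4)
        m = pp.fit(t, t.feature_names, pp.ModelSpec(kind="ensemble", n_trees=5, seed=4))
        pp.save_model(m, tmp_path / "m.json")
        other = random_table(11, 25, 4)
        with pytest.raises(ValueError, match="hash"):
            pp.load_model(tmp_path / "m.json", training_table=other)

    def test_forest_model_requires_training_table(self, tmp_path):
        t = random_table(12, 20, 3)
        m = pp.fit(t, t.feature_names, pp.ModelSpec(kind="forest", n_trees=5, seed=1))
        pp.save_model(m, tmp_path / "m.json")
        with pytest.raises(ValueError, match="training table"):
            pp.load_model(tmp_path / "m.json")


def test_linear_coefficient_recovery_within_3_se():
    """On synthetic linear data with mild noise the OLS coefficients must lie
    within 3 standard errors of the generating coefficients in >= 95% of
    seeded replicates."""
    beta = np.array([1.0, 0.8, 0.7, 0.6, 0.5])
    noise_sd = 0.1 * float(np.sqrt(np.sum(beta**2)))  # 10% of sd(X beta)
    ok = 0
    n_rep = 200
    for seed in range(n_rep):
        spec = pp.SyntheticSpec(
            seed=seed,
            n_noise=0,
            n_scarce_decoys=0,
            n_extreme_decoys=0,
            n_lowvar_decoys=0,
            nonlinear_strength=0.0,
            noise_sd=noise_sd,
        )
        table, truth = pp.generate(spec)
        m = pp.fit(table, truth.informative, pp.ModelSpec(kind="linear"))
        resid = table.ci - pp.predict(m, table)
        n, p = table.n_chemicals, len(truth.informative)
        sigma2 = resid @ resid / (n - p - 1)
        X1 = np.column_stack([np.ones(n), table.values])
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X1.T @ X1)))[1:]
        ok += bool(np.all(np.abs(m.linear_coef - beta) <= 3 * se))
    assert ok / n_rep >= 0.95
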