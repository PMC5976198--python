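"""Metrics, learners, cross-validation, selection and model comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from srisoscape.regression import (
    CVScheme,
    LinearLearner,
    MeanLearner,
    ablate,
    compare_models,
    cross_validate,
    make_learner,
    partial_dependence,
    permutation_importance,
    r_squared,
    register_learner,
    rmse,
    select_variables,
    train,
)
from srisoscape.samples import RegressionMatrix


def make_matrix(X, y, names=None, categorical=(), coords=None, seed=0):
    """Build a RegressionMatrix from raw arrays."""
    X = np.asarray(X, dtype=float)
    names = names or [f"c{j}" for j in range(X.shape[1])]
    if coords is None:
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 1000, (len(X), 2))
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "y", coords[:, 1])
    df.insert(0, "x", coords[:, 0])
    df["ratio"] = np.asarray(y, dtype=float)
    df.index = pd.Index([f"s{i}" for i in range(len(X))], name="site_id")
    return RegressionMatrix(df, list(names), list(categorical))


class TestMetrics:
    def test_rmse_hand_example(self):
        # obs (0.710, 0.712) vs pred (0.711, 0.711): both errors 0.001
        assert rmse([0.710, 0.712], [0.711, 0.711]) == pytest.approx(0.001)

    def test_rmse_zero_on_perfect(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_r2_pearson_invariant_to_affine_prediction(self):
        obs = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        pred = 2.0 * obs + 7.0  # perfectly correlated, badly biased
        assert r_squared(obs, pred) == pytest.approx(1.0)
        assert r_squared(obs, pred, kind="ss") < 0.0  # ss version punishes bias

    def test_r2_ss_hand_value(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.0, 2.0, 4.0])  # SSE 1, SST 2
        assert r_squared(obs, pred, kind="ss") == pytest.approx(0.5)

    def test_degenerate_r2_is_nan(self):
        assert np.isnan(r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestLearners:
    def test_mean_learner_cv_rmse_near_target_sd(self):
        rng = np.random.default_rng(1)
        y = 0.71 + 0.001 * rng.standard_normal(10_000)
        m = make_matrix(rng.standard_normal((10_000, 2)), y)
        res = cross_validate(m, "mean", CVScheme(k=5, repeats=1))
        assert res.mean_rmse == pytest.approx(np.std(y), rel=0.02)

    def test_linear_learner_recovers_exact_coefficients(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 3))
        y = 0.7 + 0.01 * X[:, 0] - 0.02 * X[:, 2]
        lin = LinearLearner().fit(X, y)
        np.testing.assert_allclose(lin.predict(X), y, atol=1e-10)

    def test_vif_screening_drops_duplicated_column(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        X = np.column_stack([x, x + 1e-9 * rng.standard_normal(100),
                             rng.standard_normal(100)])
        lin = LinearLearner().fit(X, 2 * x)
        assert len(lin.keep_) == 2  # one of the twins removed
        np.testing.assert_allclose(lin.predict(X), 2 * x, atol=1e-5)

    def test_categorical_one_hot_fits_group_means(self):
        rng = np.random.default_rng(4)
        codes = rng.integers(0, 3, 300).astype(float)
        means = {0.0: 0.705, 1.0: 0.711, 2.0: 0.716}
        y = np.vectorize(means.get)(codes)
        m = make_matrix(codes[:, None], y, names=["litho"],
                        categorical=["litho"])
        learner = make_learner("glm", 0, m).fit(m.X, m.y)
        pred = learner.predict(np.array([[0.0], [1.0], [2.0]]))
        np.testing.assert_allclose(pred, [0.705, 0.711, 0.716], atol=1e-10)

    def test_rf_learns_step_function(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (400, 2))
        y = np.where(X[:, 0] > 0.5, 0.715, 0.705)
        m = make_matrix(X, y)
        res = cross_validate(m, {"name": "rf", "n_estimators": 100},
                             CVScheme(k=5, repeats=1))
        assert res.mean_rmse < 0.002

    def test_rf_explicit_max_features_skips_search(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.standard_normal((50, 4)), rng.standard_normal(50))
        t = train(m, {"name": "rf", "max_features": 2, "n_estimators": 20},
                  scheme=None)
        assert t.learner.max_features_ == 2

    def test_unknown_learner_rejected(self):
        m = make_matrix(np.zeros((5, 1)), np.zeros(5))
        with pytest.raises(KeyError, match="nope"):
            make_learner("nope", 0, m)

    def test_registry_extension(self):
        class Shift:
            uses_coords = False

            def fit(self, X, y, coords=None):
                return self

            def predict(self, X, coords=None):
                return np.asarray(X)[:, 0] + 1.0

        register_learner("shift", lambda seed, matrix, **kw: Shift())
        m = make_matrix(np.arange(10.0)[:, None], np.arange(10.0) + 1.0)
        res = cross_validate(m, "shift", CVScheme(k=2, repeats=1))
        assert res.mean_rmse == 0.0


class TestCVScheme:
    def test_fold_assignment_shapes_and_balance(self):
        scheme = CVScheme(k=10, repeats=5, seed=3)
        a = scheme.fold_assignments(100)
        assert a.shape == (5, 100)
        for r in range(5):
            counts = np.bincount(a[r], minlength=10)
            assert counts.min() == counts.max() == 10

    def test_deterministic_and_shared_across_models(self):
        scheme = CVScheme(k=4, repeats=2, seed=9)
        np.testing.assert_array_equal(scheme.fold_assignments(37),
                                      scheme.fold_assignments(37))

    def test_repeats_differ(self):
        a = CVScheme(k=5, repeats=2, seed=0).fold_assignments(50)
        assert not np.array_equal(a[0], a[1])

    def test_train_fraction_leaves_rows_out(self):
        a = CVScheme(k=5, repeats=1, train_fraction=0.8, seed=0).fold_assignments(100)
        assert (a[0] == -1).sum() == 20

    def test_more_folds_than_sites_rejected(self):
        with pytest.raises(ValueError):
            CVScheme(k=10, repeats=1).fold_assignments(5)


class TestSelection:
    def _informative_matrix(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 4))
        # c0 strong, c1 weak-but-real, c2/c3 pure noise
        y = 0.71 + 0.01 * X[:, 0] + 0.002 * X[:, 1] \
            + 0.0005 * rng.standard_normal(n)
        return make_matrix(X, y)

    def test_noise_columns_discarded(self):
        m = self._informative_matrix()
        sel = select_variables(m, {"name": "rf", "n_estimators": 100,
                                   "max_features": 2},
                               CVScheme(k=5, repeats=1), seed=1)
        assert "c0" in sel
        assert "c2" not in sel and "c3" not in sel

    def test_single_covariate_short_circuits(self):
        m = make_matrix(np.random.default_rng(0).standard_normal((30, 1)),
                        np.zeros(30))
        assert select_variables(m) == ["c0"]

    def test_all_noise_returns_one_covariate(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.standard_normal((100, 3)), rng.standard_normal(100))
        sel = select_variables(m, {"name": "rf", "n_estimators": 50,
                                   "max_features": 1},
                               CVScheme(k=5, repeats=1), seed=2)
        assert len(sel) == 1

    def test_permutation_importance_identity_model(self):
        # For predict(X) = X[:,0] with y = X[:,0], shuffling column 0 makes
        # the error sqrt(2)*sd (difference of two independent copies); the
        # noise column has exactly zero importance.
        class Identity:
            uses_coords = False

            def fit(self, X, y, coords=None):
                return self

            def predict(self, X, coords=None):
                return np.asarray(X)[:, 0]

        register_learner("ident", lambda seed, matrix, **kw: Identity())
        rng = np.random.default_rng(11)
        x = rng.standard_normal(5000)
        m = make_matrix(np.column_stack([x, rng.standard_normal(5000)]), x)
        t = train(m, "ident", scheme=None)
        imp = permutation_importance(t, seed=0, n_repeats=3)
        imp = imp.set_index("covariate")["importance"]
        assert imp["c0"] == pytest.approx(np.sqrt(2) * np.std(x), rel=0.05)
        assert imp["c1"] == 0.0

    def test_partial_dependence_stump(self):
        # A hand-built threshold model has a step-shaped partial dependence.
        class Stump:
            uses_coords = False

            def fit(self, X, y, coords=None):
                return self

            def predict(self, X, coords=None):
                return np.where(np.asarray(X)[:, 0] > 0.5, 1.0, 0.0)

        register_learner("stump", lambda seed, matrix, **kw: Stump())
        rng = np.random.default_rng(12)
        m = make_matrix(rng.uniform(0, 1, (50, 2)), np.zeros(50))
        t = train(m, "stump", scheme=None)
        pd_ = partial_dependence(t, "c0", probe_values=[0.2, 0.8, 1.5])
        assert pd_["mean_prediction"].tolist() == [0.0, 1.0, 1.0]
        assert pd_["extrapolated"].tolist() == [False, False, True]
        assert len(pd_.attrs["deciles"]) == 9

    def test_partial_dependence_unknown_covariate(self):
        m = make_matrix(np.zeros((30, 1)), np.zeros(30))
        t = train(m, "mean", scheme=None)
        with pytest.raises(KeyError):
            partial_dependence(t, "zzz")


def _brute_wilcoxon_two_sided(diff):
    """Exact two-sided signed-rank p by sign-flip enumeration."""
    d = np.asarray(diff, float)
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats_all = []
    for signs in itertools.product([0, 1], repeat=n):
        stats_all.append(ranks[np.array(signs, bool)].sum())
    stats_all = np.array(stats_all)
    mu = ranks.sum() / 2.0
    p = np.mean(np.abs(stats_all - mu) >= abs(w_obs - mu) - 1e-12)
    return p


class TestComparison:
    def test_matches_signflip_enumeration(self):
        rng = np.random.default_rng(13)
        for trial in range(5):
            diff = rng.standard_normal(10)
            # wrap the diffs into two CVMetrics objects with shared folds
            from srisoscape.regression import CVMetrics
            assign = CVScheme(k=10, repeats=1, seed=trial).fold_assignments(40)
            base = rng.uniform(1, 2, 10)
            ta = pd.DataFrame({"repeat": 0, "fold": np.arange(10),
                               "rmse": base + diff, "r2": 0.5, "n_test": 4})
            tb = pd.DataFrame({"repeat": 0, "fold": np.arange(10),
                               "rmse": base, "r2": 0.5, "n_test": 4})
            res = compare_models(CVMetrics(ta, assign), CVMetrics(tb, assign))
            assert res.p_value == pytest.approx(
                _brute_wilcoxon_two_sided(diff), abs=1e-10)

    def test_identical_models_p_one(self):
        from srisoscape.regression import CVMetrics
        assign = CVScheme(k=5, repeats=1).fold_assignments(20)
        t = pd.DataFrame({"repeat": 0, "fold": np.arange(5), "rmse": 1.0,
                          "r2": 0.5, "n_test": 4})
        res = compare_models(CVMetrics(t, assign), CVMetrics(t.copy(), assign))
        assert res.p_value == 1.0 and res.median_difference == 0.0

    def test_mismatched_folds_rejected(self):
        from srisoscape.regression import CVMetrics
        a1 = CVScheme(k=5, repeats=1, seed=0).fold_assignments(20)
        a2 = CVScheme(k=5, repeats=1, seed=1).fold_assignments(20)
        t = pd.DataFrame({"repeat": 0, "fold": np.arange(5), "rmse": 1.0,
                          "r2": 0.5, "n_test": 4})
        with pytest.raises(ValueError, match="fold assignments"):
            compare_models(CVMetrics(t, a1), CVMetrics(t.copy(), a2))

    def test_clear_winner_detected(self):
        rng = np.random.default_rng(14)
        X = rng.uniform(0, 1, (300, 2))
        y = 0.71 + 0.01 * X[:, 0] + 0.0005 * rng.standard_normal(300)
        m = make_matrix(X, y)
        scheme = CVScheme(k=5, repeats=2, seed=5)
        good = cross_validate(m, {"name": "rf", "n_estimators": 100,
                                  "max_features": 1}, scheme)
        bad = cross_validate(m, "mean", scheme)
        res = compare_models(good, bad)
        assert res.a_better and res.p_value < 0.01


class TestAblation:
    def test_dropping_informative_covariate_hurts(self):
        rng = np.random.default_rng(15)
        X = rng.uniform(0, 1, (300, 3))
        y = 0.71 + 0.01 * X[:, 0] + 0.0005 * rng.standard_normal(300)
        m = make_matrix(X, y)
        scheme = CVScheme(k=5, repeats=1, seed=2)
        spec = {"name": "rf", "n_estimators": 100, "max_features": 1}
        full = cross_validate(m, spec, scheme)
        without = ablate(m, spec, scheme, drop=["c0"])
        assert without.mean_rmse > 2 * full.mean_rmse

    def test_unknown_or_total_drop_rejected(self):
        m = make_matrix(np.zeros((30, 2)), np.zeros(30))
        with pytest.raises(ValueError, match="unknown"):
            ablate(m, "mean", CVScheme(k=2, repeats=1), drop=["qq"])
        with pytest.raises(ValueError, match="every covariate"):
            ablate(m, "mean", CVScheme(k=2, repeats=1), drop=["c0", "c1"])


class TestTrainedModel:
    def test_residuals_definition(self):
        rng = np.random.default_rng(16)
        m = make_matrix(rng.standard_normal((40, 1)),
                        0.71 + 0.001 * rng.standard_normal(40))
        t = train(m, "mean", scheme=None)
        np.testing.assert_allclose(t.residuals, m.y - m.y.mean(), atol=1e-12)

    def test_cv_metrics_attached_and_summary_keys(self):
        rng = np.random.default_rng(17)
        m = make_matrix(rng.standard_normal((60, 1)), rng.standard_normal(60))
        t = train(m, "mean", scheme=CVScheme(k=3, repeats=2))
        s = t.cv.summary()
        assert set(s) == {"mean_rmse", "sd_rmse", "mean_r2", "sd_r2", "n_folds"}
        assert s["n_folds"] == 6
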