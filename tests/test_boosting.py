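"""The boosted-ensemble engine: growth, prediction, influence, serialization."""

import numpy as np
import pandas as pd
import pytest

from painmgmt.boosting import (
    BRTModel,
    BRTParams,
    FitError,
    fit_brt,
    predict_prob,
    predict_raw,
    relative_influence,
)

from conftest import make_stump_model


def _expit(z):
    return 1 / (1 + np.exp(-z))


class TestParams:
    def test_defaults_carry_the_published_settings(self):
        p = BRTParams()
        assert (p.n_trees, p.learning_rate, p.tree_complexity) == (1000, 0.01, 10)
        assert (p.predictor_fraction, p.train_fraction) == (0.5, 0.75)

    @pytest.mark.parametrize("kw", [{"predictor_fraction": 0.0},
                                    {"train_fraction": 1.2},
                                    {"tree_complexity": 0}])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            BRTParams(**kw)


class TestFitValidation:
    def test_single_class_outcome_rejected(self):
        X = np.zeros((20, 3))
        with pytest.raises(FitError, match="single-class"):
            fit_brt(X, np.ones(20), BRTParams(n_trees=5, train_fraction=1.0))

    def test_nonbinary_and_missing_outcomes_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(FitError):
            fit_brt(X, np.array([0.0, 1.0, 2.0, 0.0]))
        with pytest.raises(FitError):
            fit_brt(X, np.array([0.0, 1.0, np.nan, 0.0]))

    def test_nonfinite_predictors_rejected(self):
        X = np.zeros((4, 2))
        X[0, 0] = np.inf
        with pytest.raises(FitError, match="non-finite"):
            fit_brt(X, np.array([0.0, 1.0, 0.0, 1.0]))


class TestPrediction:
    def test_zero_tree_model_predicts_the_intercept(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        y = (rng.random(30) < 0.4).astype(float)
        m = fit_brt(X, y, BRTParams(n_trees=0, train_fraction=1.0))
        np.testing.assert_allclose(predict_prob(m, X), _expit(m.intercept))
        assert m.intercept == pytest.approx(np.log(y.mean() / (1 - y.mean())))

    def test_duplicated_rows_get_identical_predictions(self, small_fit):
        model, coded = small_fit
        X2 = pd.concat([coded.X.iloc[[5]], coded.X.iloc[[5]]])
        p = predict_prob(model, X2)
        assert p[0] == p[1]

    def test_hand_built_stump_evaluates_by_hand(self):
        m = make_stump_model(["a", "b"], [(0, 0.5, -1.0, 2.0, False, 1.0)],
                             intercept=0.25)
        X = pd.DataFrame({"a": [0.0, 1.0, np.nan], "b": [9.0, 9.0, 9.0]})
        raw = predict_raw(m, X)
        np.testing.assert_allclose(raw, [0.25 - 1.0, 0.25 + 2.0, 0.25 + 2.0])
        assert ((predict_prob(m, X) > 0) & (predict_prob(m, X) < 1)).all()

    def test_missing_branch_direction_is_respected(self):
        m = make_stump_model(["a"], [(0, 0.5, -1.0, 2.0, True, 1.0)])
        X = pd.DataFrame({"a": [np.nan]})
        assert predict_raw(m, X)[0] == -1.0

    def test_column_mismatch_names_the_offenders(self, small_fit):
        model, coded = small_fit
        bad = coded.X.rename(columns={"fam_yoga": "fam_hot_yoga"})
        with pytest.raises(ValueError, match="fam_yoga"):
            predict_prob(model, bad)


class TestTrainingBehaviour:
    def test_deviance_nonincreasing_with_fixed_subsample(self):
        rng = np.random.default_rng(1)
        X = (rng.random((300, 8)) < 0.5).astype(float)
        eta = 0.3 + X[:, 0] - 0.8 * X[:, 1]
        y = (rng.random(300) < _expit(eta)).astype(float)
        m = fit_brt(X, y, BRTParams(n_trees=300, bag_per_tree=False, seed=2))
        assert np.all(np.diff(m.train_deviance) <= 1e-12)
        assert m.holdout_deviance is not None  # 25% holdout diagnostic

    def test_null_data_shows_no_spurious_holdout_gain(self):
        """With y independent of X, the model cannot beat the intercept."""
        rng = np.random.default_rng(3)
        X = (rng.random((500, 10)) < 0.5).astype(float)
        y = (rng.random(500) < 0.5).astype(float)
        m = fit_brt(X, y, BRTParams(bag_per_tree=False, seed=0))
        yh = y[m.holdout_index]
        p0 = y[m.train_index].mean()
        baseline = -2 * np.mean(yh * np.log(p0) + (1 - yh) * np.log(1 - p0))
        assert m.holdout_deviance >= baseline - 0.02
        assert m.holdout_deviance <= baseline + 0.35

    def test_fit_is_deterministic_given_seed(self, clean_coded):
        p = BRTParams(n_trees=40, seed=11)
        m1 = fit_brt(clean_coded.X, clean_coded.y, p)
        m2 = fit_brt(clean_coded.X, clean_coded.y, p)
        np.testing.assert_array_equal(
            predict_prob(m1, clean_coded.X), predict_prob(m2, clean_coded.X)
        )

    def test_tree_complexity_bounds_split_count(self, clean_coded):
        m = fit_brt(clean_coded.X, clean_coded.y, BRTParams(n_trees=20, seed=0))

        def count_splits(node):
            if "feature" not in node:
                return 0
            return 1 + count_splits(node["left"]) + count_splits(node["right"])

        assert all(count_splits(t) <= 10 for t in m.trees)

    def test_missing_values_are_handled_without_imputation(self, small_coded):
        cc = small_coded.complete_outcome()
        m = fit_brt(cc.X, cc.y, BRTParams(n_trees=60, seed=1))
        p = predict_prob(m, cc.X)
        assert np.isfinite(p).all()


class TestRelativeInfluence:
    def test_sums_to_100(self, small_fit):
        model, _ = small_fit
        ri = relative_influence(model)
        assert ri.per_predictor.sum() == pytest.approx(100.0, abs=1e-6)
        assert (ri.per_predictor >= 0).all()

    def test_single_split_predictor_takes_everything(self):
        m = make_stump_model(["a", "b", "c"], [(0, 0.5, -1, 1, False, 3.0),
                                               (0, 0.5, -1, 1, False, 5.0)])
        ri = relative_influence(m)
        assert ri.per_predictor["a"] == pytest.approx(100.0)
        assert ri.per_predictor["b"] == 0.0

    def test_hand_set_improvements_split_80_20(self):
        m = make_stump_model(["A", "B"], [(0, 0.5, -1, 1, False, 8.0),
                                          (1, 0.5, -1, 1, False, 2.0)])
        ri = relative_influence(m)
        assert ri.per_predictor["A"] == pytest.approx(80.0)
        assert ri.per_predictor["B"] == pytest.approx(20.0)

    def test_threshold_is_100_over_p(self, small_fit):
        model, _ = small_fit
        assert relative_influence(model).threshold == pytest.approx(100 / 37)
        assert round(relative_influence(model).threshold, 1) == 2.7

    def test_unfitted_model_rejected(self):
        m = make_stump_model(["a"], [])
        with pytest.raises(ValueError, match="no trees"):
            relative_influence(m)


def test_json_round_trip_preserves_predictions(tmp_path, small_fit):
    model, coded = small_fit
    path = tmp_path / "model.json"
    model.to_json(path)
    back = BRTModel.from_json(path)
    np.testing.assert_array_equal(
        predict_prob(model, coded.X), predict_prob(back, coded.X)
    )
    assert back.params == model.params
    assert back.predictor_names == model.predictor_names


def test_matches_reference_boosting_on_shared_settings():
    """Depth-1, no subsampling: agrees with scikit-learn to 1e-8."""
    from sklearn.ensemble import GradientBoostingClassifier

    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 3))
    y = (rng.random(30) < _expit(0.8 * X[:, 0] - 0.5 * X[:, 1])).astype(float)
    params = BRTParams(n_trees=25, learning_rate=0.1, tree_complexity=1,
                       predictor_fraction=1.0, train_fraction=1.0,
                       min_samples_leaf=1, leaf_clamp=None, seed=0)
    mine = fit_brt(X, y, params)
    ref = GradientBoostingClassifier(
        n_estimators=25, learning_rate=0.1, max_depth=1, min_samples_leaf=1,
        subsample=1.0, max_features=None,
    ).fit(X, y)
    np.testing.assert_allclose(
        predict_prob(mine, X), ref.predict_proba(X)[:, 1], atol=1e-8
    )
    np.testing.assert_allclose(mine.train_deviance, ref.train_score_, atol=1e-8)


def test_alternative_sampling_flags_fit_cleanly(clean_coded):
    """Per-split feature draws and the fixed-subsample mode both converge."""
    for params in (BRTParams(n_trees=40, features_per_split=True, seed=0),
                   BRTParams(n_trees=40, bag_per_tree=False, seed=0)):
        m = fit_brt(clean_coded.X, clean_coded.y, params)
        p = predict_prob(m, clean_coded.X)
        assert np.isfinite(p).all()
        assert m.train_deviance[-1] < m.train_deviance[0]
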