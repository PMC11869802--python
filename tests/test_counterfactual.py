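"""Counterfactual scenarios, the reduction statistic, bootstrap, and search."""

import numpy as np
import pandas as pd
import pytest

from painmgmt.boosting import predict_prob
from painmgmt.counterfactual import (
    Scenario,
    ScenarioError,
    apply_scenario,
    combined_scenarios,
    estimate_reduction,
    exhaustive_best_set,
    iterative_search,
    preset_all_benefits,
    preset_all_familiarity,
    reduction_point,
)
from painmgmt.schema import SurveySchema, build_coded_matrix
from painmgmt.simulate import GeneratorConfig, generate_survey

from conftest import make_stump_model


def _expit(z):
    return 1 / (1 + np.exp(-z))


def _logit(p):
    return np.log(p / (1 - p))


def constant_model(names, p):
    """Zero-tree model predicting a constant probability p."""
    return make_stump_model(list(names), [], intercept=float(_logit(p)))


class TestApplyScenario:
    def test_empty_scenario_is_identity(self):
        X = pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, np.nan]})
        out = apply_scenario(X, Scenario({}))
        pd.testing.assert_frame_equal(out, X)

    def test_override_is_idempotent_on_constant_column(self):
        X = pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 1.0]})
        out = apply_scenario(X, Scenario({"a": 1.0}))
        pd.testing.assert_frame_equal(out, X)

    def test_override_fills_every_row_and_leaves_input_untouched(self):
        X = pd.DataFrame({"a": [0.0, 1.0, np.nan, 0.0]})
        out = apply_scenario(X, Scenario({"a": 1.0}))
        assert out["a"].sum() == 4.0
        assert X["a"].sum() == 1.0  # original unmodified

    def test_unknown_predictor_rejected(self):
        with pytest.raises(ScenarioError, match="zzz"):
            apply_scenario(pd.DataFrame({"a": [1.0]}), Scenario({"zzz": 1.0}))


class TestReductionPoint:
    def test_direct_formula(self):
        # N_O = 100 observed users, constant model giving N_S = 77
        X = pd.DataFrame({"a": np.zeros(200)})
        y = np.r_[np.ones(100), np.zeros(100)]
        m = constant_model(["a"], 77 / 200)
        n_o, n_s, rs = reduction_point(m, X, y, Scenario({}))
        assert (n_o, n_s) == (100.0, pytest.approx(77.0))
        assert rs == pytest.approx(23.0)

    def test_zero_reduction_when_counts_match(self):
        X = pd.DataFrame({"a": np.zeros(200)})
        y = np.r_[np.ones(100), np.zeros(100)]
        m = constant_model(["a"], 0.5)
        assert reduction_point(m, X, y, Scenario({}))[2] == pytest.approx(0.0)

    def test_increase_reports_negative_reduction(self):
        X = pd.DataFrame({"a": np.zeros(200)})
        y = np.r_[np.ones(100), np.zeros(100)]
        m = constant_model(["a"], 103.1 / 200)
        assert reduction_point(m, X, y, Scenario({}))[2] == pytest.approx(-3.1)

    def test_zero_observed_count_rejected(self):
        X = pd.DataFrame({"a": np.zeros(5)})
        m = constant_model(["a"], 0.4)
        with pytest.raises(ScenarioError, match="undefined"):
            reduction_point(m, X, np.zeros(5), Scenario({}))


class TestBootstrapEstimate:
    def make_fixture(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": (rng.random(300) < 0.5).astype(float),
                          "b": (rng.random(300) < 0.5).astype(float)})
        y = (rng.random(300) < _expit(0.4 - 0.9 * X["a"])).astype(float).to_numpy()
        model = make_stump_model(["a", "b"], [(0, 0.5, 0.4, -0.5, False, 1.0)])
        return model, X, y

    def test_same_seed_reproduces_estimate(self):
        model, X, y = self.make_fixture()
        s = Scenario({"a": 1.0})
        e1 = estimate_reduction(model, X, y, s, n_bootstrap=100, seed=9)
        e2 = estimate_reduction(model, X, y, s, n_bootstrap=100, seed=9)
        np.testing.assert_array_equal(e1.replicates, e2.replicates)
        assert e1.ci95 == e2.ci95

    def test_point_is_exact_mean_of_replicates(self):
        model, X, y = self.make_fixture()
        est = estimate_reduction(model, X, y, Scenario({"a": 1.0}),
                                 n_bootstrap=50, seed=1)
        assert est.point_percent == est.replicates.mean()

    def test_ci_is_type7_percentile(self):
        model, X, y = self.make_fixture()
        est = estimate_reduction(model, X, y, Scenario({"a": 1.0}),
                                 n_bootstrap=200, seed=2)
        lo, hi = np.percentile(est.replicates, [2.5, 97.5])
        assert est.ci95 == (pytest.approx(lo), pytest.approx(hi))

    def test_unused_predictor_gives_bit_identical_predictions_and_zero_rs(self):
        """Overriding a predictor absent from every split changes nothing."""
        model, X, y = self.make_fixture()
        s = Scenario({"b": 1.0})  # the single tree only splits on "a"
        np.testing.assert_array_equal(
            predict_prob(model, X), predict_prob(model, apply_scenario(X, s))
        )
        est = estimate_reduction(model, X, y, s, n_bootstrap=100, seed=3,
                                 n_observed_mode="predicted")
        assert np.all(est.replicates == 0.0)
        assert est.ci95 == (0.0, 0.0)

    def test_zero_outcome_resamples_are_redrawn_with_warning(self):
        X = pd.DataFrame({"a": np.zeros(4)})
        y = np.array([1.0, 0.0, 0.0, 0.0])
        m = constant_model(["a"], 0.25)
        with pytest.warns(UserWarning, match="redrawn"):
            est = estimate_reduction(m, X, y, Scenario({}), n_bootstrap=300, seed=0)
        assert est.n_redrawn > 0
        assert np.isfinite(est.replicates).all()

    def test_threshold_count_mode(self):
        model, X, y = self.make_fixture()
        est = estimate_reduction(model, X, y, Scenario({"a": 1.0}),
                                 n_bootstrap=20, seed=0, count_mode="threshold")
        assert float(est.n_scenario).is_integer()


class TestCombinedScenarios:
    def test_union_of_null_scenarios_is_null(self):
        model, X, y = TestBootstrapEstimate().make_fixture()
        ests = combined_scenarios(model, X, y,
                                  [[Scenario({"b": 1.0}), Scenario({"b": 0.0})]],
                                  n_bootstrap=50, seed=0)
        # later overrides win; "b" never splits, so nothing changes either way
        assert ests[0].scenario.overrides == {"b": 0.0}

    def test_combined_beats_singles_with_independent_protective_effects(self):
        model = make_stump_model(
            ["a", "b"],
            [(0, 0.5, 0.5, -0.6, False, 1.0), (1, 0.5, 0.4, -0.5, False, 1.0)],
        )
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": (rng.random(400) < 0.5).astype(float),
                          "b": (rng.random(400) < 0.5).astype(float)})
        y = (rng.random(400) < 0.6).astype(float)
        single_a, single_b, both = combined_scenarios(
            model, X, y,
            [Scenario({"a": 1.0}), Scenario({"b": 1.0}),
             [Scenario({"a": 1.0}), Scenario({"b": 1.0})]],
            n_bootstrap=100, seed=4,
        )
        assert both.point_percent >= single_a.point_percent - 0.5
        assert both.point_percent >= single_b.point_percent - 0.5

    def test_presets_cover_their_item_sets(self):
        sch = SurveySchema.default()
        fam = preset_all_familiarity(sch)
        ben = preset_all_benefits(sch)
        assert len(fam.overrides) == 19
        assert all(k.startswith("fam_") for k in fam.overrides)
        assert len(ben.overrides) == 10
        assert all(k.startswith("benefit_") for k in ben.overrides)


class TestIterativeSearch:
    def additive_model(self):
        # independent additive protective effects of known sizes
        return make_stump_model(
            ["a", "b", "c", "d"],
            [(0, 0.5, 0.45, -0.9, False, 1.0),
             (1, 0.5, 0.3, -0.6, False, 1.0),
             (2, 0.5, 0.15, -0.3, False, 1.0)],
        )

    def fixture(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({c: (rng.random(500) < 0.5).astype(float)
                          for c in ["a", "b", "c", "d"]})
        y = (rng.random(500) < 0.6).astype(float)
        return X, y

    def test_max_i_zero_gives_empty_path(self):
        X, y = self.fixture()
        path = iterative_search(self.additive_model(), X, y, ["a", "b"], max_i=0,
                                n_bootstrap=10, seed=0)
        assert path.steps == []

    def test_greedy_orders_by_effect_size(self):
        X, y = self.fixture()
        path = iterative_search(self.additive_model(), X, y, ["d", "c", "b", "a"],
                                max_i=3, n_bootstrap=20, seed=0)
        assert [s[0] for s in path.steps] == ["a", "b", "c"]
        pts = [s[1].point_percent for s in path.steps]
        assert pts[0] < pts[1] < pts[2]  # cumulative reductions accumulate

    def test_greedy_agrees_with_exhaustive_on_additive_effects(self):
        X, y = self.fixture()
        model = self.additive_model()
        path = iterative_search(model, X, y, ["a", "b", "c", "d"], max_i=2,
                                n_bootstrap=10, seed=0)
        greedy_set = {s[0] for s in path.steps}
        best_set, _ = exhaustive_best_set(model, X, y, ["a", "b", "c", "d"], 2)
        assert greedy_set == set(best_set)

    def test_ties_break_by_pool_order(self):
        # two candidates the model never splits on: both give exactly 0
        model = make_stump_model(["a", "b", "c", "d"],
                                 [(0, 0.5, 0.2, -0.4, False, 1.0)])
        X, y = self.fixture()
        path = iterative_search(model, X, y, ["c", "b"], max_i=1,
                                n_bootstrap=10, seed=0)
        assert path.steps[0][0] == "c"

    def test_pool_overflow_rejected(self):
        X, y = self.fixture()
        with pytest.raises(ScenarioError, match="max_i"):
            iterative_search(self.additive_model(), X, y, ["a"], max_i=2)
        with pytest.raises(ScenarioError, match="exhaustive"):
            exhaustive_best_set(self.additive_model(), X, y, list("abcdefghijklm"), 2)


def test_model_results_interface_runs_the_full_stack():
    """Counterfactuals through the fitted-results object on synthetic data."""
    from painmgmt.boosting import BRTParams
    from painmgmt.model import PharmUseBRT

    cfg = GeneratorConfig(
        n_respondents=300, seed=21, baseline_logit=0.6,
        effects={"fam_mindful_breathing_meditation": -0.9},
    ).without_missingness()
    coded = build_coded_matrix(generate_survey(cfg), cfg.schema)
    res = PharmUseBRT.from_coded(coded, params=BRTParams(n_trees=120, seed=0)).fit()
    est = res.estimate_reduction(Scenario.single("fam_mindful_breathing_meditation"),
                                 n_bootstrap=60, seed=1)
    assert est.point_percent > 0  # protective effect recovered in sign
    text = res.summary()
    assert "relative influence" in text
    assert "1000" not in text.split("trees:")[0]  # header reports actual settings


def test_refit_bootstrap_mode_runs():
    """The expensive refit-per-replicate bootstrap produces sane estimates."""
    from painmgmt.boosting import BRTParams, fit_brt

    cfg = GeneratorConfig(
        n_respondents=150, seed=13, baseline_logit=0.6,
        effects={"fam_mindful_breathing_meditation": -0.9},
    ).without_missingness()
    coded = build_coded_matrix(generate_survey(cfg), cfg.schema)
    model = fit_brt(coded.X, coded.y, BRTParams(n_trees=30, seed=0))
    est = estimate_reduction(model, coded.X, coded.y.to_numpy(),
                             Scenario.single("fam_mindful_breathing_meditation"),
                             n_bootstrap=8, seed=0, refit=True)
    assert np.isfinite(est.replicates).all()
    assert est.n_bootstrap == 8
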