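import numpy as np
import pandas as pd
import pytest

from painmgmt.boosting import BRTParams, fit_brt
from painmgmt.schema import SurveySchema, build_coded_matrix
from painmgmt.simulate import GeneratorConfig, generate_survey


@pytest.fixture(scope="session")
def default_schema():
    return SurveySchema.default()


@pytest.fixture(scope="session")
def small_survey():
    """195 synthetic respondents under the default (table-margin) generator."""
    cfg = GeneratorConfig(n_respondents=195, seed=42)
    return generate_survey(cfg), cfg


@pytest.fixture(scope="session")
def small_coded(small_survey):
    records, cfg = small_survey
    return build_coded_matrix(records, cfg.schema)


@pytest.fixture(scope="session")
def clean_coded():
    """Missingness-free coded data with a couple of real effects (n=400)."""
    cfg = GeneratorConfig(
        n_respondents=400,
        seed=7,
        baseline_logit=0.5,
        effects={"fam_mindful_breathing_meditation": -0.9,
                 "pain_difficult_activities": 1.0},
    ).without_missingness()
    return build_coded_matrix(generate_survey(cfg), cfg.schema)


@pytest.fixture(scope="session")
def small_fit(clean_coded):
    """A quick default-structure fit (fewer trees) for reuse across tests."""
    params = BRTParams(n_trees=150, seed=3)
    model = fit_brt(clean_coded.X, clean_coded.y, params)
    return model, clean_coded


def make_stump_model(feature_names, splits, intercept=0.0, learning_rate=1.0):
    """Hand-built single-split-per-tree ensemble for exact expectations.

    ``splits`` is a list of (feature index, threshold, gamma_left,
    gamma_right, missing_left, gain).
    """
    from painmgmt.boosting import BRTModel, BRTParams

    trees = []
    gains = {name: 0.0 for name in feature_names}
    for j, thr, gl, gr, miss_left, gain in splits:
        trees.append(
            {
                "feature": j,
                "threshold": thr,
                "missing_left": miss_left,
                "left": {"value": gl},
                "right": {"value": gr},
            }
        )
        gains[feature_names[j]] += gain
    params = BRTParams(n_trees=len(trees), learning_rate=learning_rate,
                       tree_complexity=1, predictor_fraction=1.0,
                       train_fraction=1.0)
    return BRTModel(
        intercept=intercept,
        trees=trees,
        params=params,
        predictor_names=list(feature_names),
        train_index=np.arange(0),
        train_deviance=np.zeros(len(trees)),
        holdout_index=np.arange(0),
        holdout_deviance=None,
        split_gains=gains,
    )
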