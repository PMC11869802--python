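"""Ground-truth validation benchmarks for the pipeline.

These protocols exercise the full stack — generator, coding, boosted
ensemble, counterfactual bootstrap — against quantities that are exactly
computable from the synthetic generating model, so estimator bias, interval
coverage and selection behaviour can be measured rather than assumed.

The recovery benchmark uses a compact 16-predictor schema (six familiarity
items including the three pharmacological ones, two benefits, four
pain/training items, four demographics) with a single planted protective
familiarity effect of -0.7 log-odds at 50% prevalence and ~65% baseline
outcome prevalence, n = 1000 respondents and no missingness: large enough
for the effect to be identifiable, small enough to enumerate the exact
truth.
"""

from __future__ import annotations

import numpy as np

from .boosting import BRTParams, fit_brt
from .counterfactual import Scenario, estimate_reduction, iterative_search
from .descriptives import odds_ratio
from .schema import SurveySchema, build_coded_matrix
from .simulate import (
    DEFAULT_BENEFIT_PREV,
    DEFAULT_FAMILIARITY_PREV,
    DEFAULT_NONPHARM_USE_PREV,
    GeneratorConfig,
    exact_reduction_enumeration,
    generate_survey,
)

__all__ = [
    "RECOVERY_EFFECT",
    "recovery_schema",
    "recovery_config",
    "recovery_scenario",
    "recovery_truth",
    "run_recovery_replicates",
    "run_greedy_selection_replicates",
    "null_grid_type1_rate",
]

#: the planted protective familiarity effect, in log-odds
RECOVERY_EFFECT = -0.7
_RECOVERY_COLUMN = "fam_mindful_breathing_meditation"


def recovery_schema() -> SurveySchema:
    """Compact 16-predictor schema for the recovery benchmark."""
    return SurveySchema(
        approaches=(
            "otc_medications",
            "prescription_opioids",
            "illicit_opioids",
            "prescription_nonopioid",
            "mindful_breathing_meditation",
            "physical_therapy",
        ),
        benefits=("unpaid_leave", "paid_disability"),
    )


def recovery_config(seed: int, n: int = 1000) -> GeneratorConfig:
    """Generator with one planted -0.7 familiarity effect, no missingness."""
    sch = recovery_schema()
    fam = {a: DEFAULT_FAMILIARITY_PREV[a] for a in sch.approaches}
    fam["mindful_breathing_meditation"] = 0.5
    return GeneratorConfig(
        n_respondents=n,
        seed=seed,
        baseline_logit=0.97,  # ~65% baseline outcome prevalence
        effects={_RECOVERY_COLUMN: RECOVERY_EFFECT},
        familiarity_prevalences=fam,
        benefit_prevalences={b: DEFAULT_BENEFIT_PREV[b] for b in sch.benefits},
        nonpharm_use_prevalences={
            a: v for a, v in DEFAULT_NONPHARM_USE_PREV.items() if a in sch.approaches
        },
        schema=sch,
    ).without_missingness()


def recovery_scenario() -> Scenario:
    return Scenario.single(_RECOVERY_COLUMN, 1.0)


def recovery_truth() -> float:
    """Exact percent reduction under the recovery scenario, by enumeration."""
    return exact_reduction_enumeration(recovery_config(seed=0), recovery_scenario())


def run_recovery_replicates(
    n_replicates: int = 50,
    n_bootstrap: int = 200,
    seed: int = 0,
    n: int = 1000,
    params: BRTParams | None = None,
):
    """Fit and estimate on fresh synthetic samples; return points and CIs.

    Each replicate draws a new survey, codes it, fits the ensemble with
    default hyperparameters, and bootstrap-estimates the reduction under the
    planted scenario. Returns (points, ci_low, ci_high, truth).
    """
    scen = recovery_scenario()
    truth = recovery_truth()
    pts = np.empty(n_replicates)
    lo = np.empty(n_replicates)
    hi = np.empty(n_replicates)
    for rep in range(n_replicates):
        rep_seed = (seed * 1009 + rep) % (2**31)
        cfg = recovery_config(seed=rep_seed, n=n)
        coded = build_coded_matrix(generate_survey(cfg), cfg.schema)
        p = params if params is not None else BRTParams(seed=rep_seed)
        model = fit_brt(coded.X, coded.y, p)
        est = estimate_reduction(
            model, coded.X, coded.y, scen, n_bootstrap=n_bootstrap, seed=rep_seed
        )
        pts[rep], (lo[rep], hi[rep]) = est.point_percent, est.ci95
    return pts, lo, hi, truth


GREEDY_POOL = (
    "fam_mindful_breathing_meditation",
    "fam_music_therapy",
    "fam_body_scans",
    "fam_yoga",
    "fam_biofeedback",
    "benefit_unpaid_leave",
    "benefit_paid_disability",
    "benefit_paid_vacation",
    "benefit_onsite_first_aid",
    "opioid_risk_training",
)


def run_greedy_selection_replicates(
    n_replicates: int = 20, seed: int = 0, n: int = 1000
) -> int:
    """How often greedy step 1 picks the single causal factor among 9 nulls.

    Uses the default 37-predictor schema with one planted -0.7 familiarity
    effect; returns the number of replicates selecting the causal factor.
    """
    hits = 0
    for rep in range(n_replicates):
        rep_seed = (seed * 2003 + rep) % (2**31)
        cfg = GeneratorConfig(
            n_respondents=n,
            seed=rep_seed,
            baseline_logit=0.62,
            effects={_RECOVERY_COLUMN: RECOVERY_EFFECT},
        ).without_missingness()
        coded = build_coded_matrix(generate_survey(cfg), cfg.schema)
        model = fit_brt(coded.X, coded.y, BRTParams(seed=rep_seed))
        path = iterative_search(
            model, coded.X, coded.y, list(GREEDY_POOL),
            max_i=1, n_bootstrap=20, seed=rep_seed,
        )
        hits += path.steps[0][0] == _RECOVERY_COLUMN
    return hits


def null_grid_type1_rate(n_cells: int = 1000, n: int = 150, seed: int = 0,
                         alpha: float = 0.05) -> float:
    """Empirical false-positive rate of the OR significance test under the null.

    Simulates independent binary outcome/group pairs and reports the share
    of cells flagged at the given alpha by the likelihood-ratio test.
    """
    rng = np.random.Generator(np.random.Philox(key=seed))
    flags = 0
    done = 0
    while done < n_cells:
        y = (rng.random(n) < 0.5).astype(float)
        g = (rng.random(n) < 0.5).astype(float)
        try:
            res = odds_ratio(y, g)
        except ValueError:
            continue  # degenerate draw; redraw
        flags += res.p_value < alpha
        done += 1
    return flags / n_cells
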