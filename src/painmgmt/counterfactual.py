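"""Counterfactual reduction estimates from a fitted boosted ensemble.

A *scenario* forces one or more coded predictors to fixed values for every
respondent — "all workers are familiar with meditation", "all workers have
paid disability leave" — and the fitted model is used to predict the number
of workers who would use pharmacological pain management under that
hypothetical. With N_O the observed count of users and N_S the expected
count under the scenario (the sum of predicted probabilities on the modified
predictor table), the percent reduction is

    R_S = (N_O - N_S) / N_O * 100

Positive values are reductions; negative values are increases. Uncertainty
comes from a nonparametric bootstrap: respondents are resampled with
replacement, (N_O, N_S, R_S) are recomputed on each resample with the fixed
fitted model, and the estimate is the mean of the bootstrap replicates with
a 2.5th-97.5th percentile interval.

These are model-based predicted reductions on cross-sectional data, not
identified causal effects: no exchangeability or positivity argument is
made, and the numbers say what the fitted predictive model implies, nothing
stronger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .boosting import BRTModel, predict_prob
from .schema import SurveySchema

__all__ = [
    "Scenario",
    "ReductionEstimate",
    "IterativePath",
    "apply_scenario",
    "reduction_point",
    "estimate_reduction",
    "combined_scenarios",
    "iterative_search",
    "exhaustive_best_set",
    "preset_all_familiarity",
    "preset_all_benefits",
    "preset_most_important",
]


class ScenarioError(ValueError):
    """Raised for scenarios referencing unknown predictors or impossible data."""


@dataclass(frozen=True)
class Scenario:
    """A set of predictor-value overrides applied to every respondent."""

    overrides: dict
    label: str = ""

    def __or__(self, other: "Scenario") -> "Scenario":
        merged = {**self.overrides, **other.overrides}
        label = " + ".join(s for s in (self.label, other.label) if s)
        return Scenario(overrides=merged, label=label)

    @classmethod
    def single(cls, predictor: str, value: float = 1.0) -> "Scenario":
        return cls(overrides={predictor: value}, label=predictor)


@dataclass
class ReductionEstimate:
    """Bootstrap estimate of the percent reduction R_S under a scenario."""

    scenario: Scenario
    n_observed: float
    n_scenario: float
    point_percent: float
    ci95: tuple
    replicates: np.ndarray
    n_bootstrap: int
    n_redrawn: int = 0

    @property
    def significant(self) -> bool:
        """True when the 95% interval excludes zero."""
        lo, hi = self.ci95
        return lo > 0.0 or hi < 0.0

    def as_dict(self) -> dict:
        return {
            "label": self.scenario.label,
            "overrides": dict(self.scenario.overrides),
            "n_observed": self.n_observed,
            "n_scenario": self.n_scenario,
            "point_percent": self.point_percent,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "n_bootstrap": self.n_bootstrap,
        }


@dataclass
class IterativePath:
    """Greedy accumulation of the best intervention set, one factor per step."""

    steps: list  # list of (added factor, cumulative ReductionEstimate)
    candidate_pool: list

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for i, (factor, est) in enumerate(self.steps, start=1):
            rows.append(
                {
                    "step": i,
                    "added_factor": factor,
                    "point_percent": est.point_percent,
                    "ci95_low": est.ci95[0],
                    "ci95_high": est.ci95[1],
                }
            )
        return pd.DataFrame(rows)


def _check_columns(X: pd.DataFrame, scenario: Scenario) -> None:
    unknown = [c for c in scenario.overrides if c not in X.columns]
    if unknown:
        raise ScenarioError(f"scenario predictors not in data: {unknown}")


def apply_scenario(X: pd.DataFrame, scenario: Scenario) -> pd.DataFrame:
    """Return a copy of ``X`` with the scenario's overrides applied to all rows."""
    _check_columns(X, scenario)
    Xs = X.copy()
    for col, val in scenario.overrides.items():
        Xs[col] = float(val)
    return Xs


def _counts(model, X, y, scenario, n_observed_mode, count_mode):
    y = np.asarray(y, dtype=float)
    p_s = predict_prob(model, apply_scenario(X, scenario))
    if count_mode == "threshold":
        contrib_s = (p_s >= 0.5).astype(float)
    elif count_mode == "expected":
        contrib_s = p_s
    else:
        raise ScenarioError(f"unknown count_mode {count_mode!r}")
    if n_observed_mode == "observed":
        contrib_o = y
    elif n_observed_mode == "predicted":
        p_o = predict_prob(model, X)
        contrib_o = (p_o >= 0.5).astype(float) if count_mode == "threshold" else p_o
    else:
        raise ScenarioError(f"unknown n_observed_mode {n_observed_mode!r}")
    return contrib_o, contrib_s


def reduction_point(
    model: BRTModel,
    X: pd.DataFrame,
    y_observed,
    scenario: Scenario,
    n_observed_mode: str = "observed",
    count_mode: str = "expected",
):
    """Point estimate: (N_O, N_S, R_S) with the fixed fitted model.

    By default N_O is the observed count of the outcome and N_S the expected
    count under the scenario (sum of predicted probabilities on the modified
    table). ``n_observed_mode="predicted"`` replaces N_O with the model's
    predicted count on the unmodified table, a sensitivity variant that
    isolates the scenario's effect from calibration drift;
    ``count_mode="threshold"`` counts predictions at a 0.5 cutoff instead of
    summing probabilities.
    """
    contrib_o, contrib_s = _counts(model, X, y_observed, scenario, n_observed_mode, count_mode)
    n_obs = float(np.nansum(contrib_o))
    if n_obs == 0:
        raise ScenarioError("observed outcome count is zero; R_S is undefined")
    n_scen = float(contrib_s.sum())
    return n_obs, n_scen, (n_obs - n_scen) / n_obs * 100.0


def estimate_reduction(
    model: BRTModel,
    X: pd.DataFrame,
    y,
    scenario: Scenario,
    n_bootstrap: int = 1000,
    seed: int = 0,
    n_observed_mode: str = "observed",
    count_mode: str = "expected",
    refit: bool = False,
) -> ReductionEstimate:
    """Bootstrap estimate of R_S: mean and type-7 percentile 95% interval.

    Respondents are resampled with replacement; each replicate recomputes
    (N_O, N_S, R_S) with the fixed fitted model (``refit=True`` refits the
    ensemble on every resample instead — far more expensive). Replicates
    with N_O = 0 are redrawn (counted; a warning is emitted if they exceed
    1% of draws). Deterministic given ``seed``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_obs, n_scen, _ = reduction_point(
        model, X, y, scenario, n_observed_mode=n_observed_mode, count_mode=count_mode
    )
    contrib_o, contrib_s = _counts(model, X, y, scenario, n_observed_mode, count_mode)

    rng = np.random.Generator(np.random.Philox(key=seed))
    reps = np.empty(n_bootstrap)
    redrawn = 0
    for b in range(n_bootstrap):
        while True:
            idx = rng.integers(0, n, size=n)
            n_o = contrib_o[idx].sum()
            if n_o > 0:
                break
            redrawn += 1
        if refit:
            from .boosting import fit_brt
            from dataclasses import replace as _replace

            params_b = _replace(model.params, seed=int(rng.integers(0, 2**31 - 1)))
            model_b = fit_brt(X.iloc[idx], y[idx], params_b)
            co_b, cs_b = _counts(
                model_b, X.iloc[idx], y[idx], scenario, n_observed_mode, count_mode
            )
            reps[b] = (co_b.sum() - cs_b.sum()) / co_b.sum() * 100.0
        else:
            reps[b] = (n_o - contrib_s[idx].sum()) / n_o * 100.0
    if redrawn > 0.01 * n_bootstrap:
        warnings.warn(
            f"{redrawn} bootstrap resamples had zero observed outcomes and were redrawn",
            stacklevel=2,
        )
    lo, hi = np.percentile(reps, [2.5, 97.5])  # type-7 linear interpolation
    return ReductionEstimate(
        scenario=scenario,
        n_observed=n_obs,
        n_scenario=n_scen,
        point_percent=float(reps.mean()),
        ci95=(float(lo), float(hi)),
        replicates=reps,
        n_bootstrap=n_bootstrap,
        n_redrawn=redrawn,
    )


def combined_scenarios(
    model: BRTModel,
    X: pd.DataFrame,
    y,
    scenario_sets: list,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> list:
    """One ReductionEstimate per scenario set (overrides applied jointly).

    Each element of ``scenario_sets`` is a Scenario or a list of Scenarios
    whose overrides are unioned. Every set reuses the same seed so estimates
    differ only through the scenarios themselves.
    """
    out = []
    for s in scenario_sets:
        if isinstance(s, (list, tuple)):
            merged = s[0]
            for extra in s[1:]:
                merged = merged | extra
            s = merged
        out.append(estimate_reduction(model, X, y, s, n_bootstrap=n_bootstrap, seed=seed))
    return out


def iterative_search(
    model: BRTModel,
    X: pd.DataFrame,
    y,
    candidate_pool: list,
    max_i: int | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
    forced_value: float = 1.0,
) -> IterativePath:
    """Greedy forward search for the best set of i intervention factors.

    At step i every remaining candidate is tentatively added to the current
    override set and the one with the largest point-estimate R_S is kept
    (ties broken by candidate order in the pool); the kept cumulative set
    then gets a full bootstrap estimate. ``candidate_pool`` lists predictor
    columns; each is forced to ``forced_value``.
    """
    pool = list(candidate_pool)
    if max_i is None:
        max_i = len(pool)
    if max_i > len(pool):
        raise ScenarioError("max_i exceeds candidate pool size")
    steps = []
    current: dict = {}
    labels: list = []
    for _ in range(max_i):
        best_factor, best_rs = None, -np.inf
        for cand in pool:
            if cand in current:
                continue
            trial = Scenario({**current, cand: forced_value})
            _, _, rs = reduction_point(model, X, y, trial)
            if rs > best_rs:  # strict: first candidate in pool order wins ties
                best_factor, best_rs = cand, rs
        if best_factor is None:
            break
        current[best_factor] = forced_value
        labels.append(best_factor)
        cum = Scenario(dict(current), label=" + ".join(labels))
        est = estimate_reduction(model, X, y, cum, n_bootstrap=n_bootstrap, seed=seed)
        steps.append((best_factor, est))
    return IterativePath(steps=steps, candidate_pool=pool)


def exhaustive_best_set(
    model: BRTModel,
    X: pd.DataFrame,
    y,
    candidate_pool: list,
    set_size: int,
    forced_value: float = 1.0,
    max_pool: int = 12,
):
    """Best intervention set of a given size by brute-force enumeration.

    A guard against greedy suboptimality on small pools (<= ``max_pool``).
    Returns (best set as tuple, its point R_S).
    """
    pool = list(candidate_pool)
    if len(pool) > max_pool:
        raise ScenarioError(f"exhaustive search limited to pools of <= {max_pool}")
    best_set, best_rs = None, -np.inf
    for combo in combinations(pool, set_size):
        s = Scenario({c: forced_value for c in combo})
        _, _, rs = reduction_point(model, X, y, s)
        if rs > best_rs:
            best_set, best_rs = combo, rs
    return best_set, best_rs


# ---------------------------------------------------------------------------
# Named scenario presets
# ---------------------------------------------------------------------------

def preset_all_familiarity(schema: SurveySchema | None = None) -> Scenario:
    """All workers familiar with every approach in the schema."""
    if schema is None:
        schema = SurveySchema.default()
    return Scenario(
        overrides={c: 1.0 for c in schema.familiarity_columns},
        label="all familiarity",
    )


def preset_all_benefits(schema: SurveySchema | None = None) -> Scenario:
    """All workers have every job benefit in the schema."""
    if schema is None:
        schema = SurveySchema.default()
    return Scenario(
        overrides={c: 1.0 for c in schema.benefit_columns},
        label="all benefits",
    )


def preset_most_important(
    model: BRTModel,
    schema: SurveySchema | None = None,
    k: int = 6,
) -> Scenario:
    """The k most influential *modifiable* predictors, all forced on.

    Modifiable means familiarity items, job benefits, and training —
    demographics and pain history are not intervention targets.
    """
    from .boosting import relative_influence

    if schema is None:
        schema = SurveySchema.default()
    ri = relative_influence(model).per_predictor
    mods = [c for c in ri.sort_values(ascending=False).index if c in set(schema.modifiable_columns)]
    top = mods[:k]
    return Scenario(overrides={c: 1.0 for c in top}, label=f"most important {k} variables")
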