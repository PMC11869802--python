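"""Model/results interface over the boosted-ensemble engine.

`PharmUseBRT` is constructed from data (a coded matrix, a DataFrame, or raw
survey records) and `fit()` returns a `BRTResults` carrying the fitted
ensemble, per-iteration training deviance, relative influences with the
randomness threshold, and the counterfactual machinery:

    model = PharmUseBRT.from_records(records)          # or from_dataframe
    res = model.fit()
    print(res.summary())
    ri = res.relative_influence()
    est = res.estimate_reduction(Scenario.single("fam_mindful_breathing_meditation"))

Rows with a missing outcome are dropped at construction (reported on the
results); missing predictor values stay and are routed down per-split
missing directions inside the trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import counterfactual as cf
from .boosting import (
    BRTModel,
    BRTParams,
    RelativeInfluence,
    fit_brt,
    predict_prob,
    relative_influence,
)
from .schema import CodedMatrix, SurveySchema, build_coded_matrix

__all__ = ["PharmUseBRT", "BRTResults"]


class PharmUseBRT:
    """Boosted-regression-tree model of pharmacological pain-management use.

    Parameters
    ----------
    X : DataFrame of coded predictors (NaN = missing).
    y : binary outcome vector aligned with ``X``.
    params : BRTParams, optional — ensemble hyperparameters.
    schema : SurveySchema, optional — enables schema-aware scenario presets.
    """

    def __init__(self, X: pd.DataFrame, y, params: BRTParams | None = None,
                 schema: SurveySchema | None = None):
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        keep = y.notna()
        self.n_dropped_missing_outcome = int((~keep).sum())
        self.X = X.loc[keep]
        self.y = y.loc[keep]
        self.params = params if params is not None else BRTParams()
        self.schema = schema

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, outcome: str,
                       params: BRTParams | None = None,
                       schema: SurveySchema | None = None) -> "PharmUseBRT":
        X = frame.drop(columns=[outcome])
        return cls(X, frame[outcome], params=params, schema=schema)

    @classmethod
    def from_coded(cls, coded: CodedMatrix, params: BRTParams | None = None) -> "PharmUseBRT":
        return cls(coded.X, coded.y, params=params, schema=coded.schema)

    @classmethod
    def from_records(cls, records, params: BRTParams | None = None,
                     schema: SurveySchema | None = None) -> "PharmUseBRT":
        coded = build_coded_matrix(records, schema)
        return cls.from_coded(coded, params=params)

    def fit(self) -> "BRTResults":
        model = fit_brt(self.X, self.y, self.params)
        return BRTResults(model=model, X=self.X, y=self.y, schema=self.schema,
                          n_dropped_missing_outcome=self.n_dropped_missing_outcome)


@dataclass
class BRTResults:
    """Fitted ensemble plus the data it was fit on."""

    model: BRTModel
    X: pd.DataFrame
    y: pd.Series
    schema: SurveySchema | None = None
    n_dropped_missing_outcome: int = 0

    # -- estimates ---------------------------------------------------------
    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        return predict_prob(self.model, self.X if X is None else X)

    def relative_influence(self) -> RelativeInfluence:
        return relative_influence(self.model)

    @property
    def influence_threshold(self) -> float:
        """RI a predictor would have were influence uniform: 100/p percent."""
        return 100.0 / self.model.n_predictors

    @property
    def train_deviance(self) -> np.ndarray:
        return self.model.train_deviance

    @property
    def holdout_deviance(self) -> float | None:
        return self.model.holdout_deviance

    # -- counterfactuals ---------------------------------------------------
    def reduction_point(self, scenario: cf.Scenario, **kw):
        return cf.reduction_point(self.model, self.X, self.y, scenario, **kw)

    def estimate_reduction(self, scenario: cf.Scenario, n_bootstrap: int = 1000,
                           seed: int = 0, **kw) -> cf.ReductionEstimate:
        return cf.estimate_reduction(self.model, self.X, self.y, scenario,
                                     n_bootstrap=n_bootstrap, seed=seed, **kw)

    def combined_scenarios(self, scenario_sets, n_bootstrap: int = 1000,
                           seed: int = 0) -> list:
        return cf.combined_scenarios(self.model, self.X, self.y, scenario_sets,
                                     n_bootstrap=n_bootstrap, seed=seed)

    def iterative_search(self, candidate_pool=None, max_i: int | None = None,
                         n_bootstrap: int = 1000, seed: int = 0) -> cf.IterativePath:
        if candidate_pool is None:
            if self.schema is None:
                raise ValueError("no schema available; pass candidate_pool explicitly")
            candidate_pool = [c for c in self.schema.modifiable_columns
                              if c in self.X.columns]
        return cf.iterative_search(self.model, self.X, self.y, candidate_pool,
                                   max_i=max_i, n_bootstrap=n_bootstrap, seed=seed)

    # -- reporting ---------------------------------------------------------
    def summary(self, top: int = 12) -> str:
        """Plain-text summary: fit diagnostics and the top relative influences."""
        p = self.model.params
        ri = self.relative_influence().summary_frame().head(top)
        n_above = int((self.relative_influence().per_predictor > self.influence_threshold).sum())
        lines = [
            "Boosted regression tree model of pharmacological pain-management use",
            "=" * 68,
            f"observations: {len(self.y)}   (dropped for missing outcome: "
            f"{self.n_dropped_missing_outcome})",
            f"outcome prevalence: {self.y.mean():.3f}",
            f"predictors: {self.model.n_predictors}",
            f"trees: {p.n_trees}  learning rate: {p.learning_rate}  "
            f"tree complexity: {p.tree_complexity}",
            f"predictor fraction/tree: {p.predictor_fraction}  "
            f"training fraction: {p.train_fraction}  seed: {p.seed}",
            f"training deviance: {self.train_deviance[0]:.4f} -> "
            f"{self.train_deviance[-1]:.4f}"
            if len(self.train_deviance) else "training deviance: (no trees)",
        ]
        if self.holdout_deviance is not None:
            lines.append(f"holdout deviance (diagnostic): {self.holdout_deviance:.4f}")
        lines += [
            "",
            f"relative influence (top {top}; randomness threshold "
            f"{self.influence_threshold:.1f}%, {n_above} predictors above)",
            "-" * 68,
        ]
        for name, row in ri.iterrows():
            flag = "*" if row["above_threshold"] else " "
            lines.append(f"  {name:<38s} {row['relative_influence_pct']:6.2f}% {flag}")
        return "\n".join(lines)

    def save(self, path) -> None:
        self.model.to_json(path)
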