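"""Synthetic survey microdata with a known outcome-generating model.

The generator emulates a cross-sectional convenience-sample survey of
construction workers: ~195 respondents, Likert familiarity/use items for 19
pain-management approaches, ten job-benefit items, yes/no pain and training
items, four categorical demographics, and per-item missingness that leaves
item denominators between roughly 138 and 195. Its purpose is to provide a
test bed with known causal structure: the binary outcome (used any
pharmacological approach) is drawn from a logistic model

    y ~ Bernoulli( expit( baseline_logit + sum_j effect_j * x_j ) )

over the *coded* (dichotomized) predictors, so the exact counterfactual
effect of any intervention on the coded predictors is computable from the
generating equation itself (`true_counterfactual_reduction`,
`exact_reduction_enumeration`). Downstream estimates can then be judged
against ground truth.

Likert levels are drawn uniformly within the side of the dichotomization
threshold, since only the dichotomized value enters the analysis. Use items
for the pharmacological approaches are drawn conditional on the generated
outcome so that recoding the records reproduces it exactly (absent
missingness). Missingness is MCAR per item by default, with an optional MAR
mode, and the physician-prescribed-opioid item follows the survey's skip
logic (only asked of respondents who saw a physician).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .schema import (
    EXTRA_DEMOGRAPHICS,
    FAMILIARITY_LEVELS,
    PAIN_ITEMS,
    USE_LEVELS,
    SurveyRecord,
    SurveySchema,
)

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "generate_survey",
    "sample_true_predictors",
    "true_counterfactual_reduction",
    "exact_reduction_enumeration",
]


class ConfigError(ValueError):
    """Raised for invalid generator configuration values."""


def _expit(z):
    return 1.0 / (1.0 + np.exp(-z))


# Dichotomized familiarity prevalences per approach. The least-familiar
# approaches (biofeedback 16%, progressive muscle relaxation 20%, illicit
# opioids 24%, CBT 29%, music therapy 34%) mirror the survey margins; the
# rest are plausible for a blue-collar sample.
DEFAULT_FAMILIARITY_PREV = {
    "otc_medications": 0.95,
    "prescription_opioids": 0.85,
    "illicit_opioids": 0.24,
    "prescription_nonopioid": 0.80,
    "topical_ointments_patches": 0.85,
    "diet_changes": 0.70,
    "physical_therapy": 0.90,
    "occupational_therapy": 0.60,
    "chiropractic_care": 0.80,
    "deep_muscle_massage": 0.75,
    "acupuncture_acupressure": 0.55,
    "yoga": 0.60,
    "mindful_breathing_meditation": 0.50,
    "body_scans": 0.30,
    "progressive_muscle_relaxation": 0.20,
    "biofeedback": 0.16,
    "cognitive_behavioral_therapy": 0.29,
    "music_therapy": 0.34,
    "spiritual_healing": 0.45,
}

# P(has benefit) = 1 - the "No X" share of the benefits table.
DEFAULT_BENEFIT_PREV = {
    "onsite_nursing": 0.12,
    "paid_sick_leave": 0.28,
    "eap_mandatory_referral": 0.27,
    "paid_vacation": 0.41,
    "unpaid_leave": 0.42,
    "paid_disability": 0.41,
    "eap_personal": 0.54,
    "onsite_first_aid": 0.68,
    "health_insurance": 0.96,
    "union_member": 0.83,
}

# Dichotomized use prevalences for nonpharmacological approaches
# (OTC 75%, diet 50%, patches 44% at the top; PMR/biofeedback at the bottom).
DEFAULT_NONPHARM_USE_PREV = {
    "otc_medications": 0.75,
    "topical_ointments_patches": 0.44,
    "diet_changes": 0.50,
    "physical_therapy": 0.35,
    "occupational_therapy": 0.12,
    "chiropractic_care": 0.30,
    "deep_muscle_massage": 0.28,
    "acupuncture_acupressure": 0.15,
    "yoga": 0.15,
    "mindful_breathing_meditation": 0.20,
    "body_scans": 0.08,
    "progressive_muscle_relaxation": 0.05,
    "biofeedback": 0.02,
    "cognitive_behavioral_therapy": 0.08,
    "music_therapy": 0.10,
    "spiritual_healing": 0.12,
}

# Among respondents with the outcome, which pharmacological approaches they
# used (at least one is guaranteed; the fallback is prescription non-opioid).
DEFAULT_PHARM_USE_GIVEN_Y = {
    "prescription_nonopioid": 0.85,
    "prescription_opioids": 0.18,
    "illicit_opioids": 0.03,
}

DEFAULT_DEMOGRAPHIC_PROBS = {
    "gender": (0.832, 0.126, 0.042),
    "race_ethnicity": (0.797, 0.109, 0.036, 0.058),
    "education": (0.255, 0.538, 0.179, 0.028),
    "work_experience": (0.552, 0.186, 0.214, 0.048),
}

# Protective familiarity/benefit/training effects plus two risk factors,
# echoing the kind of structure the analysis is meant to detect.
DEFAULT_EFFECTS = {
    "pain_difficult_activities": 1.2,
    "fam_prescription_opioids": 0.8,
    "opioid_risk_training": -0.6,
    "benefit_unpaid_leave": -0.5,
    "benefit_paid_disability": -0.4,
    "fam_mindful_breathing_meditation": -0.6,
    "fam_music_therapy": -0.5,
    "fam_body_scans": -0.45,
    "benefit_eap_personal": 0.4,
}

# MCAR per-item missingness tuned so item Ns land near the 138-195 range
# at n=195 (demographics ~143-145 answered, union 167, benefits ~157-168,
# pain items ~159-165, training 179, use items ~150-165).
def _default_missingness() -> dict:
    miss = {
        "gender": 0.27,
        "race_ethnicity": 0.29,
        "education": 0.26,
        "work_experience": 0.26,
        "job_title": 0.29,
        "job_type": 0.28,
        "born_in_us": 0.26,
        "pain_last_year": 0.0,
        "pain_difficult_activities": 0.16,
        "pain_work_caused": 0.15,
        "missed_workdays": 0.18,
        "saw_physician": 0.18,
        "opioid_risk_training": 0.08,
    }
    for b in DEFAULT_BENEFIT_PREV:
        miss[f"benefit_{b}"] = 0.14 if b == "union_member" else 0.17
    for a in DEFAULT_FAMILIARITY_PREV:
        miss[f"fam_{a}"] = 0.05
        miss[f"use_{a}"] = 0.15
    return miss


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic survey generator.

    ``effects`` maps coded predictor columns (binary ones: ``fam_*``,
    ``benefit_*``, pain/training items) to log-odds effects on the outcome.
    ``baseline_logit`` is the intercept; the default is calibrated so the
    default effect set yields ~65% observed outcome prevalence (and ~13%
    opioid use) after coding.
    """

    n_respondents: int = 195
    seed: int = 0
    baseline_logit: float = 0.78
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    familiarity_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_FAMILIARITY_PREV))
    benefit_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_BENEFIT_PREV))
    nonpharm_use_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_NONPHARM_USE_PREV))
    pharm_use_given_y: dict = field(default_factory=lambda: dict(DEFAULT_PHARM_USE_GIVEN_Y))
    demographic_probs: dict = field(default_factory=lambda: dict(DEFAULT_DEMOGRAPHIC_PROBS))
    pain_prevalence: float = 0.85
    pain_conditionals: dict = field(
        default_factory=lambda: {
            "pain_difficult_activities": 0.84,
            "pain_work_caused": 0.69,
            "missed_workdays": 0.26,
            "saw_physician": 0.43,
        }
    )
    prescribed_opioid_given_physician: float = 0.31
    training_prevalence: float = 0.55
    missingness: dict = field(default_factory=_default_missingness)
    #: optional MAR missingness: item -> (covariate column, rate if 1, rate if 0)
    missingness_mar: dict = field(default_factory=dict)
    #: when set, use items are only asked of respondents reporting pain
    pain_gated: bool = False
    schema: SurveySchema = field(default_factory=SurveySchema.default)

    def __post_init__(self):
        if self.n_respondents < 1:
            raise ConfigError("n_respondents must be >= 1")
        probs = (
            list(self.familiarity_prevalences.values())
            + list(self.benefit_prevalences.values())
            + list(self.nonpharm_use_prevalences.values())
            + list(self.pharm_use_given_y.values())
            + list(self.missingness.values())
            + [self.pain_prevalence, self.training_prevalence,
               self.prescribed_opioid_given_physician]
            + list(self.pain_conditionals.values())
        )
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability out of [0, 1]: {p!r}")
        for name, pr in self.demographic_probs.items():
            if abs(sum(pr) - 1.0) > 1e-9:
                raise ConfigError(f"demographic probabilities for {name!r} must sum to 1")

    def without_missingness(self) -> "GeneratorConfig":
        return replace(self, missingness={}, missingness_mar={})


def _rng(seed: int) -> np.random.Generator:
    # Philox: counter-based, identical streams across platforms.
    return np.random.Generator(np.random.Philox(key=seed))


def predictor_prevalence(config: GeneratorConfig, column: str) -> float:
    """Marginal prevalence of a coded binary predictor under the generator."""
    if column.startswith("fam_"):
        return config.familiarity_prevalences[column[4:]]
    if column.startswith("benefit_"):
        return config.benefit_prevalences[column[8:]]
    if column == "opioid_risk_training":
        return config.training_prevalence
    if column == "pain_last_year":
        return config.pain_prevalence
    if column in config.pain_conditionals:
        return config.pain_prevalence * config.pain_conditionals[column]
    raise ConfigError(f"no generator prevalence for predictor {column!r}")


def sample_true_predictors(config: GeneratorConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the coded predictor matrix (no missingness) from the generator.

    Demographics are ordinal level codes; every other predictor is 0/1.
    Pain follow-up items are drawn conditional on pain in the last year.
    """
    schema = config.schema
    cols = {}
    for name, pr in config.demographic_probs.items():
        cols[name] = rng.choice(len(pr), size=n, p=np.asarray(pr, dtype=float)).astype(float)
    for b in schema.benefits:
        cols[f"benefit_{b}"] = (rng.random(n) < config.benefit_prevalences[b]).astype(float)
    pain = (rng.random(n) < config.pain_prevalence).astype(float)
    for p in schema.pain_predictors:
        if p == "pain_last_year":
            cols[p] = pain
        elif p == "opioid_risk_training":
            cols[p] = (rng.random(n) < config.training_prevalence).astype(float)
        elif p in config.pain_conditionals:
            cols[p] = pain * (rng.random(n) < config.pain_conditionals[p]).astype(float)
        else:
            raise ConfigError(f"no generating rule for pain predictor {p!r}")
    for a in schema.approaches:
        cols[f"fam_{a}"] = (rng.random(n) < config.familiarity_prevalences[a]).astype(float)
    return pd.DataFrame(cols, columns=schema.predictor_columns)


def _linear_predictor(config: GeneratorConfig, X: pd.DataFrame) -> np.ndarray:
    lp = np.full(len(X), config.baseline_logit, dtype=float)
    for col, eff in config.effects.items():
        if col not in X.columns:
            raise ConfigError(f"effect on unknown predictor {col!r}")
        lp += eff * X[col].to_numpy()
    return lp


def generate_survey(config: GeneratorConfig) -> list[SurveyRecord]:
    """Generate survey records; deterministic given ``config.seed``."""
    rng = _rng(config.seed)
    n = config.n_respondents
    schema = config.schema
    truth = sample_true_predictors(config, n, rng)
    tcol = {c: truth[c].to_numpy() for c in truth.columns}
    p_outcome = _expit(_linear_predictor(config, truth))
    y = (rng.random(n) < p_outcome).astype(float)

    extra_demo_probs = {
        "job_title": (0.36, 0.18, 0.14, 0.09, 0.08, 0.05, 0.10),
        "job_type": (0.55, 0.30, 0.15),
        "born_in_us": (0.96, 0.04),
    }
    extra_codes = {
        name: rng.choice(len(pr), size=n, p=np.asarray(pr, dtype=float))
        for name, pr in extra_demo_probs.items()
    }

    # Pain follow-ups not in the predictor set, drawn conditional on pain.
    pain = tcol["pain_last_year"]
    pain_extra = {}
    for item in ("pain_difficult_activities", "pain_work_caused",
                 "missed_workdays", "saw_physician"):
        if item in tcol:
            pain_extra[item] = tcol[item]
        else:
            pain_extra[item] = pain * (
                rng.random(n) < config.pain_conditionals.get(item, 0.0)
            )
    rx_by_md = pain_extra["saw_physician"] * (
        rng.random(n) < config.prescribed_opioid_given_physician
    )

    # Likert levels drawn uniformly within the dichotomized side:
    # familiarity positive side is indices 1..4, negative is 0; use positive
    # side is indices 2..4 ("occasionally"+), negative is 0..1.
    fam_level_idx = {}
    for a in schema.approaches:
        flag = tcol[f"fam_{a}"] == 1.0
        fam_level_idx[a] = np.where(flag, rng.integers(1, 5, size=n), 0)

    pharm = list(schema.pharmacological)
    used_flags = {}
    if pharm:
        draws = np.column_stack(
            [rng.random(n) < config.pharm_use_given_y.get(a, 0.0) for a in pharm]
        )
        none_used = ~draws.any(axis=1)
        fallback = (
            pharm.index("prescription_nonopioid")
            if "prescription_nonopioid" in pharm
            else 0
        )
        draws[none_used, fallback] = True
        for j, a in enumerate(pharm):
            used_flags[a] = draws[:, j] & (y == 1.0)
    for a in schema.approaches:
        if a not in used_flags:
            used_flags[a] = rng.random(n) < config.nonpharm_use_prevalences.get(a, 0.0)
    use_level_idx = {
        a: np.where(used_flags[a], rng.integers(2, 5, size=n), rng.integers(0, 2, size=n))
        for a in schema.approaches
    }

    ask_use = np.ones(n, dtype=bool) if not config.pain_gated else pain == 1.0

    records: list[SurveyRecord] = []
    for i in range(n):
        rec = SurveyRecord(respondent_id=f"R{i:05d}")
        for name, levels in schema.demographics.items():
            rec.demographics[name] = levels[int(tcol[name][i])]
        for name, levels in EXTRA_DEMOGRAPHICS.items():
            rec.demographics[name] = levels[int(extra_codes[name][i])]
        for b in schema.benefits:
            rec.benefits[b] = "present" if tcol[f"benefit_{b}"][i] == 1.0 else "absent"
        rec.pain_items["pain_last_year"] = "yes" if pain[i] == 1.0 else "no"
        for item, arr in pain_extra.items():
            rec.pain_items[item] = "yes" if arr[i] == 1.0 else "no"
        if pain_extra["saw_physician"][i] == 1.0:
            rec.pain_items["prescribed_opioid_by_physician"] = (
                "yes" if rx_by_md[i] == 1.0 else "no"
            )
        rec.pain_items["opioid_risk_training"] = (
            "yes" if tcol["opioid_risk_training"][i] == 1.0 else "no"
        )
        for a in schema.approaches:
            rec.familiarity[a] = FAMILIARITY_LEVELS[fam_level_idx[a][i]]
        if ask_use[i]:
            for a in schema.approaches:
                rec.use[a] = USE_LEVELS[use_level_idx[a][i]]
        records.append(rec)

    _inject_missingness(records, config, rng)
    return records


def _inject_missingness(records, config: GeneratorConfig, rng) -> None:
    """MCAR per-item deletion, plus optional MAR driven by a coded covariate."""
    n = len(records)
    mar = config.missingness_mar

    def drop(rec, domain, key):
        getattr(rec, domain).pop(key, None)

    item_domains = []
    demo_names = list(config.schema.demographics) + list(EXTRA_DEMOGRAPHICS)
    for d in demo_names:
        item_domains.append((d, "demographics", d))
    for b in config.schema.benefits:
        item_domains.append((f"benefit_{b}", "benefits", b))
    for p in PAIN_ITEMS:
        if p == "prescribed_opioid_by_physician":
            continue  # governed by skip logic only
        item_domains.append((p, "pain_items", p))
    for a in config.schema.approaches:
        item_domains.append((f"fam_{a}", "familiarity", a))
        item_domains.append((f"use_{a}", "use", a))

    for item, domain, key in item_domains:
        if item in mar:
            cov, r1, r0 = mar[item]
            rates = np.empty(n)
            for i, rec in enumerate(records):
                v = _coded_covariate(rec, cov)
                rates[i] = r1 if v == 1.0 else r0
            mask = rng.random(n) < rates
        else:
            rate = config.missingness.get(item, 0.0)
            if rate == 0.0:
                continue
            mask = rng.random(n) < rate
        for i, rec in enumerate(records):
            if mask[i]:
                drop(rec, domain, key)


def _coded_covariate(rec: SurveyRecord, column: str) -> float:
    if column.startswith("benefit_"):
        return 1.0 if rec.benefits.get(column[8:]) == "present" else 0.0
    if column.startswith("fam_"):
        lvl = rec.familiarity.get(column[4:])
        return 1.0 if lvl is not None and lvl != "not_at_all" else 0.0
    return 1.0 if rec.pain_items.get(column) == "yes" else 0.0


# ---------------------------------------------------------------------------
# Ground-truth counterfactual reductions from the generating model
# ---------------------------------------------------------------------------

def _overrides_of(scenario) -> Mapping[str, float]:
    return getattr(scenario, "overrides", scenario)


def true_counterfactual_reduction(
    config: GeneratorConfig, scenario, n_mc: int, seed: int = 0
) -> float:
    """Monte-Carlo ground-truth percent reduction under a scenario.

    Draws ``n_mc`` respondents from the generating distribution and compares
    expected outcome counts with and without the scenario's overrides applied
    to the coded predictors inside the generating equation:
    ``(E[count | observed] - E[count | scenario]) / E[count | observed] * 100``.
    """
    if n_mc < 1:
        raise ConfigError("n_mc must be >= 1")
    overrides = _overrides_of(scenario)
    rng = _rng(seed)
    X = sample_true_predictors(config, n_mc, rng)
    for col in overrides:
        if col not in X.columns:
            raise ConfigError(f"scenario predictor {col!r} not in generator")
    p_obs = _expit(_linear_predictor(config, X))
    Xs = X.copy()
    for col, val in overrides.items():
        Xs[col] = float(val)
    p_cf = _expit(_linear_predictor(config, Xs))
    return float((p_obs.sum() - p_cf.sum()) / p_obs.sum() * 100.0)


def exact_reduction_enumeration(config: GeneratorConfig, scenario) -> float:
    """Exact percent reduction by enumerating all binary predictor patterns.

    Valid when every predictor carrying an effect or an override is an
    independent Bernoulli in the generator (familiarity items, benefits,
    training, pain in the last year); conditional pain follow-ups are not
    supported here.
    """
    overrides = _overrides_of(scenario)
    involved = sorted(set(config.effects) | set(overrides))
    for col in involved:
        if col in config.pain_conditionals:
            raise ConfigError(
                f"{col!r} is conditionally generated; enumeration assumes independence"
            )
    prevs = {c: predictor_prevalence(config, c) for c in involved}
    k = len(involved)
    num_obs = num_cf = 0.0
    for bits in range(2 ** k):
        pattern = {c: float((bits >> j) & 1) for j, c in enumerate(involved)}
        w = 1.0
        for c in involved:
            w *= prevs[c] if pattern[c] == 1.0 else 1.0 - prevs[c]
        lp = config.baseline_logit + sum(
            config.effects.get(c, 0.0) * pattern[c] for c in involved
        )
        lp_cf = config.baseline_logit + sum(
            config.effects.get(c, 0.0)
            * (float(overrides[c]) if c in overrides else pattern[c])
            for c in involved
        )
        num_obs += w * _expit(lp)
        num_cf += w * _expit(lp_cf)
    return float((num_obs - num_cf) / num_obs * 100.0)
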