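"""Survey variable schema, Likert scales, and dichotomization rules.

The analysis dataset is a cross-sectional occupational survey: one row per
respondent, with Likert familiarity and use items for a list of pain-management
approaches, yes/no job-benefit items, yes/no pain and training items, and
categorical demographics. This module defines the canonical schema, the rules
that turn raw Likert responses into binary analysis variables, and the coded
predictor matrix handed to the model.

Dichotomization rules
---------------------
* A respondent is *familiar* with an approach if they answered at least
  "Slightly familiar" on the five-level familiarity scale.
* A respondent *used* an approach if they answered "Occasionally",
  "Sometimes", or "Very often" on the five-level use scale ("Rarely" does
  not count as use).
* The binary outcome is 1 iff the respondent used any approach in the
  schema's pharmacological subset (prescription opioids, illicit opioids,
  prescription non-opioid medication by default; over-the-counter medication
  counts as nonpharmacological).

Missing responses propagate as missing; no imputation happens at coding time.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "FAMILIARITY_LEVELS",
    "USE_LEVELS",
    "USE_POSITIVE",
    "SurveySchema",
    "SurveyRecord",
    "CodedMatrix",
    "code_familiarity",
    "code_use",
    "build_coded_matrix",
    "records_to_frame",
    "frame_to_records",
    "write_survey_csv",
    "read_survey_csv",
]


class SchemaError(ValueError):
    """Raised when a response label or item name is not in the schema."""


# Ordered Likert scales. Position in the tuple is the ordinal rank.
FAMILIARITY_LEVELS = (
    "not_at_all",
    "slightly",
    "moderately",
    "very",
    "extremely",
)

USE_LEVELS = (
    "not_at_all",
    "rarely",
    "occasionally",
    "sometimes",
    "very_often",
)

#: Use levels that count as having used an approach.
USE_POSITIVE = frozenset({"occasionally", "sometimes", "very_often"})

#: Familiarity threshold: at least this level counts as familiar.
FAMILIARITY_THRESHOLD = "slightly"

_YES_NO = {"yes": 1.0, "no": 0.0, "present": 1.0, "absent": 0.0}

# Default 19-approach list. The pharmacological subset is the prescription
# (licit or illicit) medications; OTC medication is nonpharmacological.
DEFAULT_APPROACHES = (
    "otc_medications",
    "prescription_opioids",
    "illicit_opioids",
    "prescription_nonopioid",
    "topical_ointments_patches",
    "diet_changes",
    "physical_therapy",
    "occupational_therapy",
    "chiropractic_care",
    "deep_muscle_massage",
    "acupuncture_acupressure",
    "yoga",
    "mindful_breathing_meditation",
    "body_scans",
    "progressive_muscle_relaxation",
    "biofeedback",
    "cognitive_behavioral_therapy",
    "music_therapy",
    "spiritual_healing",
)

DEFAULT_PHARMACOLOGICAL = (
    "prescription_opioids",
    "illicit_opioids",
    "prescription_nonopioid",
)

# Ten job-benefit predictors: nine workplace benefits plus union membership.
DEFAULT_BENEFITS = (
    "onsite_nursing",
    "paid_sick_leave",
    "eap_mandatory_referral",
    "paid_vacation",
    "unpaid_leave",
    "paid_disability",
    "eap_personal",
    "onsite_first_aid",
    "health_insurance",
    "union_member",
)

# Demographics entering the default 37-predictor set, with level order.
# The first level of each is the reference level for odds-ratio comparisons.
DEFAULT_DEMOGRAPHICS = {
    "gender": ("male", "female", "other"),
    "race_ethnicity": ("nh_white", "hispanic", "nh_black", "other"),
    "education": ("associates_or_higher", "hs_grad", "trade_vocational", "no_hs"),
    "work_experience": ("gt20", "11_20", "2_10", "le1"),
}

# Extra demographics carried on records but outside the default predictor set.
EXTRA_DEMOGRAPHICS = {
    "job_title": (
        "laborers",
        "masonry",
        "managers",
        "equipment",
        "carpenters",
        "electricians",
        "other",
    ),
    "job_type": ("hourly", "supervisor", "front_line"),
    "born_in_us": ("yes", "no"),
}

# All yes/no pain, care-seeking and training items carried on a record.
PAIN_ITEMS = (
    "pain_last_year",
    "pain_difficult_activities",
    "pain_work_caused",
    "missed_workdays",
    "saw_physician",
    "prescribed_opioid_by_physician",
    "opioid_risk_training",
)

# The four pain/management/training items entering the default predictor set.
DEFAULT_PAIN_PREDICTORS = (
    "pain_last_year",
    "pain_difficult_activities",
    "pain_work_caused",
    "opioid_risk_training",
)


@dataclass(frozen=True)
class SurveySchema:
    """Canonical variable schema for the survey.

    The default schema yields exactly 37 predictors: 4 demographics,
    10 job benefits, 4 pain/management/training items, and 19 familiarity
    items. All item lists are configurable.
    """

    approaches: tuple[str, ...] = DEFAULT_APPROACHES
    pharmacological: tuple[str, ...] = DEFAULT_PHARMACOLOGICAL
    benefits: tuple[str, ...] = DEFAULT_BENEFITS
    demographics: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS)
    )
    pain_predictors: tuple[str, ...] = DEFAULT_PAIN_PREDICTORS

    def __post_init__(self):
        unknown = set(self.pharmacological) - set(self.approaches)
        if unknown:
            raise SchemaError(f"pharmacological subset not in approaches: {sorted(unknown)}")
        if len(set(self.approaches)) != len(self.approaches):
            raise SchemaError("duplicate approach names")

    # -- predictor layout -------------------------------------------------
    @property
    def familiarity_columns(self) -> list[str]:
        return [f"fam_{a}" for a in self.approaches]

    @property
    def benefit_columns(self) -> list[str]:
        return [f"benefit_{b}" for b in self.benefits]

    @property
    def use_columns(self) -> list[str]:
        return [f"use_{a}" for a in self.approaches]

    @property
    def predictor_columns(self) -> list[str]:
        """Deterministic column order: demographics, benefits, pain, familiarity."""
        return (
            list(self.demographics)
            + self.benefit_columns
            + list(self.pain_predictors)
            + self.familiarity_columns
        )

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_columns)

    @property
    def modifiable_columns(self) -> list[str]:
        """Intervenable predictors: familiarity, benefits and training.

        Demographics and pain history are not plausible intervention targets
        and are excluded from default counterfactual candidate pools.
        """
        mods = self.benefit_columns + self.familiarity_columns
        if "opioid_risk_training" in self.pain_predictors:
            mods = mods + ["opioid_risk_training"]
        return mods

    def demographic_levels(self, name: str) -> tuple[str, ...]:
        try:
            return tuple(self.demographics[name])
        except KeyError:
            raise SchemaError(f"unknown demographic: {name!r}") from None

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path=None) -> str:
        payload = {
            "approaches": list(self.approaches),
            "pharmacological": list(self.pharmacological),
            "benefits": list(self.benefits),
            "demographics": {k: list(v) for k, v in self.demographics.items()},
            "pain_predictors": list(self.pain_predictors),
        }
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SurveySchema":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            with open(source) as fh:
                payload = yaml.safe_load(fh)
        return cls(
            approaches=tuple(payload["approaches"]),
            pharmacological=tuple(payload["pharmacological"]),
            benefits=tuple(payload["benefits"]),
            demographics={k: tuple(v) for k, v in payload["demographics"].items()},
            pain_predictors=tuple(payload["pain_predictors"]),
        )

    @classmethod
    def default(cls) -> "SurveySchema":
        return cls()


@dataclass
class SurveyRecord:
    """One respondent's raw item responses.

    ``familiarity`` and ``use`` map approach name -> Likert label (or None);
    ``benefits`` maps benefit name -> "present"/"absent" (or None);
    ``pain_items`` maps item name -> "yes"/"no" (or None); ``demographics``
    maps demographic name -> level label (or None).
    """

    respondent_id: str
    demographics: dict = field(default_factory=dict)
    benefits: dict = field(default_factory=dict)
    pain_items: dict = field(default_factory=dict)
    familiarity: dict = field(default_factory=dict)
    use: dict = field(default_factory=dict)


@dataclass
class CodedMatrix:
    """Respondents x predictors table plus the binary outcome.

    ``X`` holds the coded predictors as floats with NaN for missing
    (binary 0/1 indicators; demographics as ordinal level codes).
    ``y`` is 1 iff any pharmacological approach was used; NaN when every
    pharmacological use item is missing. ``use_indicators`` carries the
    19 coded use items for descriptive comparisons; ``coding`` documents
    each column.
    """

    X: pd.DataFrame
    y: pd.Series
    use_indicators: pd.DataFrame
    coding: dict
    schema: SurveySchema

    @property
    def mask(self) -> pd.DataFrame:
        """Per-cell missingness flags for the predictor table."""
        return self.X.isna()

    def complete_outcome(self) -> "CodedMatrix":
        """Rows with an observed outcome (drops respondents with y missing)."""
        keep = self.y.notna()
        return CodedMatrix(
            X=self.X.loc[keep],
            y=self.y.loc[keep],
            use_indicators=self.use_indicators.loc[keep],
            coding=self.coding,
            schema=self.schema,
        )

    def to_csv(self, path, coding_path=None) -> None:
        out = self.X.copy()
        out.insert(0, "respondent_id", self.X.index)
        out["y_pharmacological_use"] = self.y.values
        for c in self.use_indicators.columns:
            out[c] = self.use_indicators[c].values
        out.to_csv(path, index=False)
        if coding_path is not None:
            with open(coding_path, "w") as fh:
                json.dump(self.coding, fh, indent=2)


def code_familiarity(level: str | None) -> float:
    """Dichotomize a familiarity response: 1 iff at least "slightly" familiar.

    Missing (None/NaN) propagates as NaN.
    """
    if level is None or (isinstance(level, float) and np.isnan(level)):
        return np.nan
    if level not in FAMILIARITY_LEVELS:
        raise SchemaError(f"unknown familiarity level: {level!r}")
    return float(
        FAMILIARITY_LEVELS.index(level) >= FAMILIARITY_LEVELS.index(FAMILIARITY_THRESHOLD)
    )


def code_use(freq: str | None) -> float:
    """Dichotomize a use response: 1 iff occasionally/sometimes/very often.

    "Rarely" codes to 0. Missing propagates as NaN.
    """
    if freq is None or (isinstance(freq, float) and np.isnan(freq)):
        return np.nan
    if freq not in USE_LEVELS:
        raise SchemaError(f"unknown use frequency: {freq!r}")
    return float(freq in USE_POSITIVE)


def _code_yes_no(value) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    try:
        return _YES_NO[value]
    except KeyError:
        raise SchemaError(f"unknown yes/no label: {value!r}") from None


def _code_demographic(value, levels: Sequence[str], name: str) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    try:
        return float(levels.index(value))
    except ValueError:
        raise SchemaError(f"unknown level {value!r} for demographic {name!r}") from None


def build_coded_matrix(records: Iterable[SurveyRecord], schema: SurveySchema | None = None) -> CodedMatrix:
    """Code raw survey records into the predictor matrix and outcome.

    The outcome is 1 iff any pharmacological approach has coded use 1; it is
    0 when at least one pharmacological use item is observed and none codes
    to 1; it is NaN when all pharmacological use items are missing.
    """
    if schema is None:
        schema = SurveySchema.default()
    records = list(records)
    if not records:
        raise SchemaError("empty record list")

    cols = schema.predictor_columns
    rows, y_vals, use_rows, ids = [], [], [], []
    fam_names = set(schema.approaches)
    for rec in records:
        unknown = set(rec.familiarity) - fam_names | set(rec.use) - fam_names
        if unknown:
            raise SchemaError(f"unknown approach item(s): {sorted(unknown)}")
        unknown_b = set(rec.benefits) - set(schema.benefits)
        if unknown_b:
            raise SchemaError(f"unknown benefit item(s): {sorted(unknown_b)}")
        row = {}
        for name, levels in schema.demographics.items():
            row[name] = _code_demographic(rec.demographics.get(name), levels, name)
        for b in schema.benefits:
            row[f"benefit_{b}"] = _code_yes_no(rec.benefits.get(b))
        for p in schema.pain_predictors:
            row[p] = _code_yes_no(rec.pain_items.get(p))
        for a in schema.approaches:
            row[f"fam_{a}"] = code_familiarity(rec.familiarity.get(a))
        use_row = {f"use_{a}": code_use(rec.use.get(a)) for a in schema.approaches}
        pharm = [use_row[f"use_{a}"] for a in schema.pharmacological]
        observed = [v for v in pharm if not np.isnan(v)]
        if not observed:
            y = np.nan
        else:
            y = float(any(v == 1.0 for v in observed))
        rows.append(row)
        use_rows.append(use_row)
        y_vals.append(y)
        ids.append(rec.respondent_id)

    X = pd.DataFrame(rows, index=ids, columns=cols, dtype=float)
    y = pd.Series(y_vals, index=ids, name="y_pharmacological_use", dtype=float)
    use_df = pd.DataFrame(use_rows, index=ids, columns=schema.use_columns, dtype=float)
    coding = {
        name: {"type": "ordinal", "levels": list(levels)}
        for name, levels in schema.demographics.items()
    }
    coding.update(
        {f"benefit_{b}": {"type": "binary", "meaning": "has benefit"} for b in schema.benefits}
    )
    coding.update({p: {"type": "binary", "meaning": "yes"} for p in schema.pain_predictors})
    coding.update(
        {
            f"fam_{a}": {"type": "binary", "meaning": "at least slightly familiar"}
            for a in schema.approaches
        }
    )
    coding["y_pharmacological_use"] = {
        "type": "binary",
        "meaning": f"used any of {list(schema.pharmacological)}",
    }
    return CodedMatrix(X=X, y=y, use_indicators=use_df, coding=coding, schema=schema)


# ---------------------------------------------------------------------------
# Flat CSV round-trip for survey records
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[SurveyRecord], schema: SurveySchema | None = None) -> pd.DataFrame:
    """Flatten records into one row per respondent (missing -> empty cell)."""
    if schema is None:
        schema = SurveySchema.default()
    records = list(records)
    all_demo = list(schema.demographics) + [
        d for d in EXTRA_DEMOGRAPHICS if any(d in r.demographics for r in records)
    ]
    rows = []
    for rec in records:
        row = {"respondent_id": rec.respondent_id}
        for d in all_demo:
            row[d] = rec.demographics.get(d)
        for b in schema.benefits:
            row[f"benefit_{b}"] = rec.benefits.get(b)
        for p in PAIN_ITEMS:
            if any(p in r.pain_items for r in records):
                row[p] = rec.pain_items.get(p)
        for a in schema.approaches:
            row[f"fam_{a}"] = rec.familiarity.get(a)
            row[f"use_{a}"] = rec.use.get(a)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame, schema: SurveySchema | None = None) -> list[SurveyRecord]:
    if schema is None:
        schema = SurveySchema.default()

    def get(row, key):
        if key not in row or pd.isna(row[key]):
            return None
        return row[key]

    records = []
    demo_names = list(schema.demographics) + list(EXTRA_DEMOGRAPHICS)
    for _, row in frame.iterrows():
        rec = SurveyRecord(respondent_id=str(row["respondent_id"]))
        for d in demo_names:
            v = get(row, d)
            if v is not None:
                rec.demographics[d] = v
        for b in schema.benefits:
            v = get(row, f"benefit_{b}")
            if v is not None:
                rec.benefits[b] = v
        for p in PAIN_ITEMS:
            v = get(row, p)
            if v is not None:
                rec.pain_items[p] = v
        for a in schema.approaches:
            v = get(row, f"fam_{a}")
            if v is not None:
                rec.familiarity[a] = v
            v = get(row, f"use_{a}")
            if v is not None:
                rec.use[a] = v
        records.append(rec)
    return records


def write_survey_csv(records: Iterable[SurveyRecord], path, schema: SurveySchema | None = None) -> None:
    records_to_frame(list(records), schema).to_csv(path, index=False)


def read_survey_csv(path, schema: SurveySchema | None = None) -> list[SurveyRecord]:
    frame = pd.read_csv(path, dtype=str)
    return frame_to_records(frame, schema)
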