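"""Descriptive tables and subgroup odds-ratio comparisons.

Frequency tables follow the survey-reporting convention of per-item
denominators: each item's N is the number of respondents who answered it,
so Ns vary across rows. Percents are rounded to the nearest integer with
ties to even (the convention of R's ``round``, which the printed tables this
package mirrors were produced with). Residual "other" category rows in such
tables are conventionally printed as 100 minus the siblings' rounded
percents; ``complement_percent`` reproduces that.

Subgroup comparisons use 2x2 odds ratios with Wald intervals on the log
scale, a Haldane-Anscombe 0.5 correction when any cell is empty, and a
likelihood-ratio chi-squared (G-test) p-value — equivalent to the LRT of a
one-predictor logistic regression — with a Wald p-value available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .schema import CodedMatrix, SchemaError, SurveyRecord, SurveySchema, code_use

__all__ = [
    "FrequencyTable",
    "OddsRatioResult",
    "percent",
    "complement_percent",
    "tabulate",
    "odds_ratio",
    "group_comparison_grid",
    "load_participant_table",
    "load_pain_benefit_table",
]


def percent(count: float, denom: float) -> int:
    """Integer percent, ties to even (R's rounding convention)."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    return int(round(100.0 * count / denom))


def complement_percent(sibling_percents) -> int:
    """Percent printed for a residual category: 100 minus siblings' percents."""
    return int(100 - sum(sibling_percents))


@dataclass
class FrequencyTable:
    """Rows of (label, item N, count, percent) with per-item denominators."""

    item: str
    rows: pd.DataFrame  # columns: label, item_n, count, percent
    grouping: str | None = None

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


@dataclass
class OddsRatioResult:
    """2x2 odds ratio with a Wald 95% interval on the log scale."""

    comparison: tuple  # (group level, reference level)
    odds_ratio: float
    ci95: tuple
    p_value: float
    method: str
    table: tuple  # (a, b, c, d): exposed-outcome, exposed-no, ref-outcome, ref-no
    corrected: bool = False  # Haldane-Anscombe 0.5 applied


def _item_series(records, item: str, schema: SurveySchema) -> pd.Series:
    """Extract one item across records as a label series (NaN = missing)."""
    vals = []
    for rec in records:
        if item in schema.demographics or item in ("job_title", "job_type", "born_in_us"):
            vals.append(rec.demographics.get(item))
        elif item.startswith("benefit_"):
            vals.append(rec.benefits.get(item[8:]))
        elif item.startswith("fam_"):
            vals.append(rec.familiarity.get(item[4:]))
        elif item.startswith("use_"):
            vals.append(rec.use.get(item[4:]))
        elif item in rec.pain_items or item in (
            "pain_last_year", "pain_difficult_activities", "pain_work_caused",
            "missed_workdays", "saw_physician", "prescribed_opioid_by_physician",
            "opioid_risk_training",
        ):
            vals.append(rec.pain_items.get(item))
        else:
            raise SchemaError(f"unknown item: {item!r}")
    return pd.Series(vals, dtype=object)


def tabulate(
    records,
    item: str,
    by: str | None = None,
    schema: SurveySchema | None = None,
) -> FrequencyTable:
    """Frequency table for one item, optionally split by a subgroup item.

    The denominator is the item's own N (respondents with a non-missing
    response); with ``by``, denominators are per-subgroup item Ns.
    """
    if schema is None:
        schema = SurveySchema.default()
    records = list(records)
    s = _item_series(records, item, schema)
    if s.notna().sum() == 0:
        raise SchemaError(f"item {item!r} has no observed responses")

    def one_table(series, label_prefix=None):
        obs = series.dropna()
        denom = len(obs)
        counts = obs.value_counts()
        rows = []
        for label, cnt in counts.items():
            rows.append(
                {
                    "label": label if label_prefix is None else f"{label_prefix}:{label}",
                    "item_n": denom,
                    "count": int(cnt),
                    "percent": percent(int(cnt), denom),
                }
            )
        return rows

    if by is None:
        rows = one_table(s)
    else:
        g = _item_series(records, by, schema)
        rows = []
        for level in pd.Series(g.dropna().unique()).sort_values():
            sub = s[g == level]
            if sub.notna().sum() == 0:
                continue
            rows.extend(one_table(sub, label_prefix=str(level)))
    return FrequencyTable(item=item, rows=pd.DataFrame(rows), grouping=by)


def odds_ratio(y, group, method: str = "lrt") -> OddsRatioResult:
    """Odds ratio of a binary outcome between two groups.

    ``y`` and ``group`` are equal-length binary vectors; pairs with a missing
    entry are dropped. OR = ad/bc on the 2x2 table, with a Wald 95% CI
    ``exp(log OR +- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``. If any cell is
    zero, the Haldane-Anscombe 0.5 correction is applied (flagged). The
    p-value is a likelihood-ratio G-test by default (``method="wald"`` for
    the Wald z-test).
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=float)
    if y.shape != group.shape:
        raise ValueError("y and group must have the same length")
    keep = ~(np.isnan(y) | np.isnan(group))
    y, group = y[keep], group[keep]
    if y.size == 0:
        raise ValueError("no complete pairs")
    if np.unique(group).size < 2:
        raise ValueError("a group level is absent after missing-pair removal")
    if np.unique(y).size < 2:
        raise ValueError("the outcome has a single level after missing-pair removal")

    a = float(np.sum((group == 1) & (y == 1)))
    b = float(np.sum((group == 1) & (y == 0)))
    c = float(np.sum((group == 0) & (y == 1)))
    d = float(np.sum((group == 0) & (y == 0)))

    corrected = min(a, b, c, d) == 0
    if corrected:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    or_ = (a2 * d2) / (b2 * c2)
    se = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)

    if method == "lrt":
        stat = _g_statistic(a, b, c, d)
        p = float(stats.chi2.sf(stat, df=1))
    elif method == "wald":
        z = np.log(or_) / se
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")

    return OddsRatioResult(
        comparison=(1, 0),
        odds_ratio=float(or_),
        ci95=(float(lo), float(hi)),
        p_value=p,
        method=method,
        table=(a, b, c, d),
        corrected=corrected,
    )


def _g_statistic(a, b, c, d):
    """Likelihood-ratio chi-squared of the 2x2 table.

    Identical to the deviance difference of a one-predictor logistic
    regression against the intercept-only model.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return float(2.0 * terms.sum())


def group_comparison_grid(
    coded: CodedMatrix,
    treatments: list | None = None,
    characteristics: list | None = None,
    alpha: float = 0.05,
    method: str = "lrt",
    fdr: bool = False,
) -> pd.DataFrame:
    """Treatment-use x characteristic-level grid of odds ratios.

    For every treatment-use indicator and every non-reference level of each
    characteristic, compares use odds at that level against the reference
    level (the first level in the schema). Degenerate cells — a level with
    no respondents, or no variation in use — are flagged, not errors.
    Returns a long-format frame with OR, CI, p, and a significance flag;
    ``fdr=True`` adds a Benjamini-Hochberg column.
    """
    schema = coded.schema
    if treatments is None:
        treatments = list(coded.use_indicators.columns)
    if characteristics is None:
        characteristics = list(schema.demographics)
    rows = []
    for char in characteristics:
        if char in schema.demographics:
            levels = schema.demographic_levels(char)
            x = coded.X[char]
            encod = {lvl: float(i) for i, lvl in enumerate(levels)}
        elif char in coded.X.columns:
            levels = ("0", "1")
            x = coded.X[char]
            encod = {"0": 0.0, "1": 1.0}
        else:
            raise SchemaError(f"unknown characteristic: {char!r}")
        ref = levels[0]
        for level in levels[1:]:
            sel = x.isin([encod[ref], encod[level]])
            grp = (x[sel] == encod[level]).astype(float)
            for treat in treatments:
                if treat not in coded.use_indicators.columns:
                    raise SchemaError(f"unknown treatment: {treat!r}")
                yv = coded.use_indicators.loc[sel.index[sel], treat]
                try:
                    res = odds_ratio(yv.to_numpy(), grp.to_numpy(), method=method)
                    rows.append(
                        {
                            "treatment": treat,
                            "characteristic": char,
                            "level": level,
                            "reference": ref,
                            "odds_ratio": res.odds_ratio,
                            "ci95_low": res.ci95[0],
                            "ci95_high": res.ci95[1],
                            "p_value": res.p_value,
                            "significant": res.p_value < alpha,
                            "degenerate": False,
                        }
                    )
                except ValueError:
                    rows.append(
                        {
                            "treatment": treat,
                            "characteristic": char,
                            "level": level,
                            "reference": ref,
                            "odds_ratio": np.nan,
                            "ci95_low": np.nan,
                            "ci95_high": np.nan,
                            "p_value": np.nan,
                            "significant": False,
                            "degenerate": True,
                        }
                    )
    grid = pd.DataFrame(rows)
    if fdr and len(grid):
        ok = grid["p_value"].notna()
        p = grid.loc[ok, "p_value"].to_numpy()
        m = p.size
        order = np.argsort(p)
        q = np.empty(m)
        prev = 1.0
        for rank in range(m - 1, -1, -1):
            prev = min(prev, p[order[rank]] * m / (rank + 1))
            q[order[rank]] = prev
        grid.loc[ok, "p_bh"] = q
    return grid


# ---------------------------------------------------------------------------
# Packaged fixtures transcribed from the published descriptive tables
# ---------------------------------------------------------------------------

def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("painmgmt.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_participant_table() -> pd.DataFrame:
    """Participant characteristics table (long format, printed values).

    Columns: section, label, measure, denom, count, printed_pct, note.
    ``measure`` is "n" for the characteristic's own column and pain/nonpharm/
    pharm/opioids for the subgroup columns (denominator = the level's n).
    ``note`` marks rows whose printed percent is a complement-of-siblings
    value or is internally inconsistent in the source table.
    """
    return _load_fixture("table1_participants.csv")


def load_pain_benefit_table() -> pd.DataFrame:
    """Pain, pain-management-strategy and job-benefit table (printed values)."""
    return _load_fixture("table2_pain_benefits.csv")
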