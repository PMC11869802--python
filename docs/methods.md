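# Methods

`painmgmt` reimplements, as a tested pipeline, an analysis workflow for
occupational pain-management surveys: Likert item coding, descriptive
tables and subgroup odds ratios, a gradient-boosted regression tree (BRT)
model of pharmacological pain-management use, and counterfactual bootstrap
estimates of the percent reduction in use under hypothetical interventions.
This note records the model, the numerical choices, what the synthetic
generator does and does not emulate, and the package's known limitations.

## Survey coding

Respondents rate familiarity with 19 pain-management approaches on a
five-level scale (not at all / slightly / moderately / very / extremely)
and use of the same approaches on a second five-level scale (not at all /
rarely / occasionally / sometimes / very often). Familiarity is
dichotomized at *at least slightly familiar*; use at *occasionally or more
often* — answering "rarely" does not count as use. The binary outcome is
use of any **pharmacological** approach, defined as the prescription-drug
subset {prescription opioids, illicit opioids, prescription non-opioid
medication}; over-the-counter medication is nonpharmacological. Both the
approach list and the pharmacological subset live in a configurable schema
(`SurveySchema`), whose default yields exactly 37 predictors: 4
demographics (gender, race/ethnicity, education, work experience, as
ordinal level codes), 10 job benefits (nine workplace benefits plus union
membership), 4 pain/training items, and 19 familiarity indicators.

Missing responses propagate as missing at coding time; nothing is imputed.
A respondent's outcome is missing only when all three pharmacological use
items are unanswered; such rows are dropped when the model is built (the
results object reports how many).

Two design points worth flagging. The four pain/management/training
predictors are pain in the last year, pain making activities difficult,
pain caused by work, and opioid-risk training; physician visits and
physician-prescribed opioids stay on the record but outside the default
predictor set. Demographics enter the trees as single ordinal-coded
columns rather than one-hot blocks so that relative influence aggregates
per variable; for the two nominal demographics (gender, race/ethnicity)
threshold splits on the level code are an approximation to true level-set
splits, acceptable at three or four levels because successive splits can
isolate any level.

## Descriptive tables and odds ratios

Frequency tables use per-item denominators (the number of respondents who
answered that item), matching survey-reporting convention. Percents are
rounded to the nearest integer with ties to even — the behaviour of R's
`round()`, which reproduces the published tables this package mirrors
(e.g. 5/8 prints as 62%, not 63%). Residual "other" category rows in such
tables are conventionally printed as 100 minus the siblings' rounded
percents; `complement_percent` implements that rule. The packaged
transcriptions (`painmgmt/data/table*.csv`) carry the printed values
verbatim; eight printed percents are internally inconsistent with their own
count/denominator pairs (two appear transposed between adjacent rows, the
rest likely reflect denominators from an earlier data-cleaning stage) and
are flagged in a `note` column. The acceptance test reproduces every
consistent cell exactly and pins the inconsistent set so a transcription
error still fails.

Subgroup comparisons are 2×2 odds ratios, `OR = ad/bc`, with Wald 95%
intervals `exp(log OR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))` and a
Haldane–Anscombe 0.5 correction (flagged) when a cell is empty. The
significance flag in the treatment-by-characteristic grid uses the
likelihood-ratio chi-squared (G-test) of the 2×2 table, which equals the
deviance test of a one-predictor logistic regression; a Wald test is
available by flag, and an optional Benjamini–Hochberg column exists but is
off by default because the workflow being mirrored applied no multiplicity
correction. Calibration under the null is checked empirically
(`null_grid_type1_rate`): at n = 150 per cell the measured type-I rate is
≈ 4–5%, the G-test's usual mild conservatism at modest counts.

## The boosted regression tree model

The ensemble is additive on the log-odds scale. With intercept
`F0 = log(p̄/(1−p̄))` (training prevalence), iteration m fits a regression
tree to the Bernoulli gradient residuals `r_i = y_i − p_i`, and each leaf
adds a one-step Newton value `Σr / Σp(1−p)` (clamped to |γ| ≤ 4 to guard
near-pure leaves), scaled by the learning rate. Defaults mirror the
published configuration: 1000 trees, learning rate 0.01, tree complexity
10 (at most 10 splits per tree, grown best-first by maximal squared-error
reduction on the residuals, permitting up to 10-way interactions), and a
fresh random 50% predictor subset per tree.

The "75% training sample" is implemented as a per-tree bag: each tree
trains on a fresh 75% subsample drawn without replacement, the stochastic-
gradient-boosting semantics of R's `gbm` bag fraction (the reference BRT
implementation for this workflow). The alternative reading — one fixed 75%
subsample drawn before boosting, leaving a 25% holdout whose deviance is
reported as a diagnostic — is available via `bag_per_tree=False`. The
minimum observations per leaf defaults to 10 (`gbm`'s `n.minobsinnode`),
configurable. These two choices matter: with a single fixed subsample the
counterfactual estimator inherits a large variance component (which rows
were memorized) that the fixed-model bootstrap below cannot see, and its
intervals undercover noticeably.

Missing predictor values are never imputed: every split learns a missing
direction (the child that maximizes the split's improvement receives the
missing rows) and stores it, so prediction and counterfactual modification
work on incomplete rows. Candidate thresholds are midpoints of observed
unique values; ties in split gain resolve to the first candidate in
column-then-threshold order, and ties between leaves resolve to the
earliest-created leaf, making fits bit-reproducible. All randomness flows
through a counter-based Philox generator keyed by the seed: the per-tree
bag is drawn first, then the per-tree predictor subset.

With subsampling disabled and depth-1 trees the implementation is
numerically identical (≤ 1e-8) to scikit-learn's
`GradientBoostingClassifier` in per-iteration training deviance and staged
predictions; that equivalence is asserted in the tests and recomputed by
the acceptance script, with the scikit-learn model serving only as an
independent oracle.

**Relative influence.** A predictor's influence is the sum of squared-error
improvements of every split made on it, across all trees, normalized to
sum to 100%. With p predictors, uniform influence would give each
100/p % — the *randomness threshold* (2.7% at p = 37); predictors above it
are flagged as influential. Gain-based influence mildly favours
multi-level ordinal predictors (more candidate thresholds), so the
demographics tend to sit near the threshold even under the null; the
planted-signal tests account for this by planting effects large enough to
be unambiguous (|log-odds| ≥ 0.9 at n = 1000).

## Counterfactual reductions

A scenario forces one or more coded predictors to fixed values for every
respondent (all workers familiar with meditation; all workers given paid
disability leave). With `N_O` the observed number of workers using
pharmacological approaches and `N_S = Σ p̂(x_i^scenario)` the model's
expected count on the modified table, the percent reduction is
`R_S = (N_O − N_S)/N_O × 100`; negative values are increases. Expected
counts avoid an arbitrary classification cutoff; a 0.5-threshold count
mode exists by flag. A sensitivity mode replaces `N_O` with the model's
predicted count on the unmodified table, isolating the scenario's effect
from calibration drift; in that mode a scenario touching only predictors
the ensemble never split on yields exactly zero in every bootstrap
replicate.

Uncertainty comes from a nonparametric bootstrap: respondents are resampled
with replacement, `(N_O, N_S, R_S)` recomputed per resample with the fixed
fitted model, 1000 replicates by default. The reported estimate is the
replicate mean; the interval is the 2.5th–97.5th percentile (NumPy's
default type-7 linear interpolation). Resamples with `N_O = 0` are redrawn
and counted, with a warning past 1% of draws. Refitting the ensemble
within each replicate (`refit=True`) implements the alternative reading of
"the process is replicated 1000 times"; it multiplies cost by the number
of replicates and is off by default.

Combined scenarios union their overrides; named presets cover "all
familiarity" (19 overrides), "all benefits" (10, including union
membership), and "most important modifiable variables" (the top-k
modifiable predictors by relative influence; modifiable means familiarity,
benefits and training — demographics and pain history are not intervention
targets). The iterative search greedily adds, at each step, the candidate
whose cumulative scenario maximizes the point `R_S` (ties break by pool
order; selection uses the deterministic point estimate, with the full
bootstrap run on each kept cumulative set), and an exhaustive mode
enumerates all subsets for pools of at most 12 as a guard on greedy
suboptimality.

These are model-implied predicted reductions on cross-sectional survey
data. No causal identification is claimed: there is no exchangeability or
positivity argument, and the numbers quantify what the fitted predictive
model implies about hypothetical populations, nothing stronger.

## Synthetic data and what passing tests show

The generator (`GeneratorConfig`, `generate_survey`) emulates the study
conditions: 195 respondents by default; demographic margins, benefit and
familiarity prevalences, 85% pain prevalence, and per-item MCAR
missingness tuned so item denominators land in the observed 138–195 band
(an MAR option ties one item's missingness to a covariate; the
physician-prescribed-opioid item follows the survey's skip logic). The
outcome is drawn from a logistic model over the *coded* predictors,
`y ~ Bernoulli(expit(β0 + Σ βj xj))`; the default effect set plants
protective familiarity/benefit/training effects and two risk factors, and
the default intercept 0.78 is calibrated so the coded data reproduce ~65%
pharmacological use and ~13% opioid use. Use items are then drawn
conditional on the generated outcome so recoding reproduces it exactly;
Likert levels are uniform within the side of the dichotomization threshold,
since only the dichotomized value enters any analysis.

Because the generating equation is known, exact ground truth is available:
`true_counterfactual_reduction` evaluates the percent reduction by Monte
Carlo and `exact_reduction_enumeration` by summing over all binary
predictor patterns (valid for independently generated predictors). The
recovery benchmark (`painmgmt.validation`) plants a single −0.7 log-odds
protective familiarity effect at 50% prevalence, ~65% baseline use, in a
compact 16-predictor schema at n = 1000 with no missingness — large enough
to identify the effect, small enough to enumerate the truth (12.23%
reduction). Under this benchmark the full pipeline's mean point estimate
sits within 0.7 percentage points of truth and the fixed-model percentile
intervals cover the truth for roughly 86% of replicate datasets
(85.6% +- 1.7% pooled over 450 replicates).

That ~86% — not the nominal 95% — is an honest property of the published
method, not an implementation artifact: the fixed-model bootstrap varies
the evaluation sample but not the fit, so model-fit variability and the
slight probability-scale attenuation of deep overfit ensembles are outside
the interval. The refit bootstrap closes the gap at ~200× the cost.

What the generator does *not* emulate: chain-referral/social-media
recruitment structure, within-respondent correlation of item nonresponse
(beyond the optional MAR hook), correlated familiarity across related
approaches, and any confounding between familiarity and unmeasured
pain severity. Passing tests therefore demonstrate that the pipeline
recovers known structure under clean sampling assumptions, not that the
method is robust to the selection and measurement processes of a real
convenience sample.

## Problem sizes used in validation

The committed validation runs use: oracle equivalence at n = 30 with 25
depth-1 trees; planted-effect recovery over 150 replicate surveys of
n = 1000 with 200 bootstrap resamples each; greedy-selection checks over
20 replicates of n = 1000; and null-grid calibration over 1000 simulated
2×2 cells of n = 150. These sizes put Monte-Carlo noise well below each
quantity's decision margin while keeping a full validation run in single-
digit minutes on one core.

## Known limitations

- Nominal multi-level demographics are split by ordinal threshold rather
  than level sets; with ≤ 4 levels this is a mild restriction.
- Gain-based relative influence inherits the usual cardinality bias toward
  predictors with more distinct values.
- The greedy search can be suboptimal when effects interact strongly in
  the fitted surface; the exhaustive mode exists for small pools.
- Percentile bootstrap intervals with the fixed fitted model undercover by
  several points (see above); treat them as variability bands for the
  estimate given the model, not full-uncertainty intervals.
- The counterfactual machinery deliberately makes no causal claims.
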