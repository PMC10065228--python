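# Methods

This document records the models and procedures the package implements, the
assumptions behind them, every tunable parameter with its default and
rationale, what the synthetic generator does and does not emulate, the
numerical choices, and the known limitations.

## 1. Study design

The pipeline implements a matched case-control design over coded electronic
health records, stratified by sex (one run handles one stratum).

**Case identification.** A case is any patient with an ankylosing spondylitis
(AS) code in any source — GP (prefix `N100`), hospital (`M45`), or
rheumatology (`sAS`) — with the diagnosis date taken as the *earliest* AS
mention across sources.  If an anti-TNF prescription or an HLA-B27 test /
spondyloarthropathy code precedes the first AS code, onset is back-dated to
that earlier "suspected" date, on the rationale that such records indicate
the disease process was already recognised.

**Eligibility.** Cases must be aged 15–35 inclusive at diagnosis (the typical
AS onset window; both bounds closed), diagnosed in or after 2000 (coding
practice stability), and registered at least 3 years before diagnosis (closed
boundary) so the prodromal window is observable.

**Matching.** Each case receives `ratio` (default **100**) distinct controls
of the same sex with week of birth within **±26 weeks**, each with at least 3
years of registration before and after the index date.  Controls may serve
several cases but never the same case twice.  Controls carrying any AS or
axial-spondyloarthropathy code are excluded from the pool.  The k-th match of
every case forms *control set k*, giving 100 parallel case-control cohorts
that share the case arm.

**Index date (design decision).** By default (`index_mode="calendar"`) a
control's index date *is* its matched case's diagnosis date, with feasibility
enforced at matching time.  A uniform draw from the control's feasible
interval is available (`index_mode="uniform"`) but is not the default: with
birth-week matching already in place, a uniformly drawn index date decouples
the control's age-at-index from the case's, so every purely age-graded
background code becomes informative and the matched design's null-safety is
lost.  Calendar matching keeps age-at-index balanced within pair by
construction.

**Split.** A case-level 70/30 train/test split
(`n_train = round(0.7 · n_cases)`); every control inherits its case's side so
matched sets stay intact.

## 2. Features

Binary presence flags: *did the participant have ≥1 matching event strictly
before their index date, in the window?*  Frequency is collapsed to presence
so that high-volume code types (prescriptions) cannot outweigh one-off
diagnoses.  A feature key is `concept|level|source|window`:

- **concept/level** — the code's first *L* characters for L ∈ {1,…,5}
  (mirroring a hierarchical code dictionary), plus named aggregate groups
  (level `AGG`, source `ANY`) such as `back_pain` or `pain`, defined as sets
  of code prefixes.
- **window** — default scheme: 5-year age bands `[15,20) … [30,35)` of age at
  the event, anchored at the week-of-birth midpoint (week start + 3.5 days,
  years of 365.25 days).  Alternative scheme: yearly slices y1–y3 counting
  back from the index date (`ceil(days_before/365.25)`).
- **min_count = 5** — features present in fewer than 5 participants are
  pruned; below that a 2×2 test is meaningless and the dimensionality cost is
  pure noise.

## 3. Feature selection

**Stage 1 — chi-squared stability screening.**  For each feature, a Pearson
chi-squared test (1 df, no continuity correction) of training cases against
each of the 100 training control sets: 100 tests per feature.  A feature
survives if p < `alpha` (**0.01**) in at least `stability_fraction` of the
tests — **0.90** for the larger (male) stratum, **0.75** for the smaller
(female) one, where power is lower.  The threshold count is
`ceil(fraction · n_cohorts)`.  Features more frequent in *controls* are kept
with direction −1 rather than discarded (a protective marker is still a
marker).  Tests with any expected cell below 5 are counted and flagged, not
excluded.  Because all 100 tests share the case arm they are positively
dependent; the independent-test tail bound Binom(100, 0.01) ≥ 90 (~1e−151)
is therefore only indicative, but even a distribution-free Markov bound on
the significant-test count gives P(select) ≤ 100·0.01/90 ≈ 0.011 per null
feature.

**Stage 2 — logistic Wald filter.**  Survivors are tested at
`lr_alpha = 0.01` on training cases + control set 1.  Default mode is
**univariable** (one logistic fit per feature): the hierarchical truncation
levels produce chains of identical or near-identical binary columns, and in a
joint multivariable model the coefficient splits across near-copies and the
Wald statistics become uninformative (observed at full study scale: a joint
fit retained zero features).  A joint mode remains available
(`lr_mode="joint"`).  Perfectly collinear duplicate columns are removed
before fitting; complete separation (|coef| > 15 or SE > 50) is flagged and
the feature *retained*, never silently dropped — a perfectly separating
feature is maximally informative, not absent.  Non-convergent fits fall back
to an L2-stabilised Newton solver with step-halving (λ = 1e−3) and are
flagged `ridge`.

**Stage 3 — PCA.**  The retained binary matrix is mean-centred but *not*
variance-scaled (all features share the 0/1 scale) and decomposed with a full
SVD; the smallest number of leading components whose cumulative explained
variance reaches `pca_variance_target` (**0.80**) is kept.  Components are
labelled A, B, C, … in the model output.

## 4. Model

For each of the 100 (training cases vs control set k) pairings, one CART-style
decision tree on the retained component scores: Gini impurity, `max_depth=3`,
`min_samples_leaf=10` — shallow enough to read clinically and to resist
overfitting 266 training cases.  Each candidate is then evaluated against
*all* 100 pairings; the final model is the candidate with the highest mean
**F value** (harmonic mean of sensitivity and PPV, i.e. the F1 score), ties
broken by lowest candidate index.  Leaves carry stable ids (`M1`, `F3`, …)
and their training case fraction, which serves as the continuous risk score
for ROC analysis (a hard-label tree has no other native score).

## 5. Evaluation

- The six metrics (sensitivity, specificity, PPV, NPV, accuracy, F) from 2×2
  counts; real-valued counts are allowed for expected matrices; a metric with
  a zero denominator is reported as undefined (`None`), never 0.
- **Prevalence adjustment**: closed-form Bayes rule,
  `PPV = sens·π / (sens·π + (1−spec)(1−π))`, with the flagged fraction
  `sens·π + (1−spec)(1−π)`.
- **Perfect model**: the expected confusion matrix of a hypothetical
  90%-sensitive, 90%-specific classifier applied to observed population
  totals — an upper-bound comparator (higher values would likely indicate
  overfitting).
- **ROC/AUC**: a threshold sweep over distinct score values (positive when
  score ≥ threshold), tied scores moving together; trapezoid AUC, which then
  equals the rank-based Mann–Whitney statistic exactly.
- **Generalisability**: predictions on a fresh population sample plus the
  development cases, reported with and without the development participants
  (index date = diagnosis date for cases, end of registration otherwise).

## 6. The synthetic generator

### What it emulates

- Patient demographics: sex, week of birth (snapped to Monday; born
  1982–1992), registration windows.
- A **plantable prodromal signature** per sex: a list of
  (concept, age band, case penetrance, control penetrance) items; each
  participant carries each item's concept code with the stated Bernoulli
  probability if the band intersects their registration (and, for cases,
  precedes diagnosis).  The shipped male and female signatures plant 8 items
  each across back pain, NSAID/analgesic prescribing, spinal imaging, blood
  tests, musculoskeletal codes and uveitis in the bands [15,30).
- A **background process-of-care stream**: Poisson
  (`background_code_rate = 2`/patient/year) events drawn from codes whose
  leading characters (2/6/8) are disjoint from every signal and pathway
  prefix at every truncation level, so background features are cleanly
  classifiable as null in audits.
- AS diagnosis coding at the diagnosis date (70% GP / 25% hospital / 5%
  rheumatology) and an optional **suspected pathway** (`suspected_fraction`,
  default 0.10): a random case subset receives an anti-TNF prescription or an
  HLA-B27 test + spondyloarthropathy code 30–365 days before diagnosis.
- Two modes: matched case-control generation (cases plus a matchable control
  pool, `control_pool_factor = 1.2` oversampling) and population mode
  (`population_size` with `case_prevalence = 0.0009`, heterogeneous
  registration coverage) for generalisability runs.

Diagnosis age is uniform in **[26, 31]** years by design: every default
planted band ([15,20), [20,25), [25,30)) then lies fully before every case's
index date, and a calendar-matched control index date is always feasible
inside a 15–35 registration span.  This encodes the "prodromal decade before
a twenties/thirties diagnosis" picture.

### What it does not emulate

- Visit clustering, seasonality, or code co-occurrence structure beyond the
  planted items (background codes are independent Poisson).
- Informative dropout, death, practice deregistration, or data-quality drift
  over calendar time.
- Dose, duration or free-text content of prescriptions; laboratory values.
- Correlation between signature items within a patient beyond their shared
  case status.
- Real code dictionaries: codes are synthetic strings that only *mimic* a
  hierarchical coding system's prefix structure.

## 7. Numerical choices

- All randomness flows from integer seeds through `numpy.random.SeedSequence`;
  derived stage seeds are reduced mod 2³¹.  Reruns of the same configuration
  are byte-identical (CSV with `\r\n` line endings and ISO-8601 dates; the
  manifest records a SHA-256 per artifact and excludes wall-clock time).
- Chi-squared: the vectorised Pearson formula `n(ad−bc)²/(r₁r₂c₁c₂)`;
  p-values from the χ²(1) survival function.  Degenerate tables (a zero
  margin) are reported as statistic 0, p 1, and flagged.
- Percentages are rounded half-up to 2 decimals (`decimal.Decimal`), matching
  report-style formatting; rounding happens only at the display boundary.
- Tree thresholds serialise via `repr(float)` so the text model file round-
  trips bit-exactly.
- Ties in model selection break to the lowest candidate index (`argmax`
  semantics); ROC tie blocks move along the curve together.
- Problem sizes: study conditions are 380 cases × 101 participants each
  (≈38 000 rows); the feature matrix at that scale is ≈213 columns after
  pruning; a full run takes ≈45 s on one CPU.

## 8. Limitations

- Synthetic-only validation: recovery of planted signal demonstrates the
  pipeline's statistical machinery, not clinical validity on real records.
- The stability screen's 100 tests share the case arm; the screening
  threshold's nominal binomial error rate is therefore approximate (see the
  Markov bound above).
- The univariable LR default tests features marginally; jointly redundant
  features are not pruned at that stage (PCA absorbs the redundancy
  afterwards).
- Calendar index matching ties control index dates to case diagnosis dates;
  secular trends in coding volume would be absorbed into the match rather
  than modelled.
- The leaf case fraction is a coarse, piecewise-constant risk score; ROC
  curves from a depth-3 tree have few operating points.
- The "number of chi-squared tests" is exactly `n_cohorts` per feature
  (default 100); window-count multiplicity is configurable through the
  feature scheme rather than fixed.
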