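# aspredict

Predicting a future diagnosis of ankylosing spondylitis (AS) from routinely
collected, coded primary-care and hospital records.

## The scientific problem

AS is a chronic inflammatory arthritis of the spine whose diagnosis is
commonly delayed by around eight years from symptom onset.  The years before
diagnosis leave a trail in coded electronic health records: back-pain codes,
repeat NSAID and analgesic prescriptions, spinal imaging, blood tests, and
extra-articular features such as uveitis.  This package implements a complete
pipeline that learns that prodrome from coded records and asks the question
that actually matters for deployment: *does a model that looks excellent in a
case-enriched study cohort survive contact with a general population where AS
has a prevalence of roughly 0.09%?*

The pipeline:

1. **Synthetic population** (`aspredict.synth`) — a generator of patient and
   event tables with *plantable* sex-specific prodromal signatures (concept,
   age band, case and control penetrance) over a background of uninformative
   process-of-care codes.  Because the signal is planted, recovery is exactly
   measurable.
2. **Cohort** (`aspredict.cohort`) — case identification from AS codes across
   GP, hospital and rheumatology sources with back-dating when an anti-TNF
   prescription or HLA-B27/spondyloarthropathy coding precedes the first AS
   code; eligibility (diagnosis age 15–35, year ≥ 2000, ≥ 3 years prior
   registration); 1:100 matching on sex and week of birth (± 26 weeks) with
   3-year data windows either side of the index date; a 70/30 case-level
   train/test split.
3. **Features** (`aspredict.features`) — binary presence flags per (code
   prefix at 5 specificity levels or aggregate concept group, source, time
   window), windows being 5-year age bands or pre-index year slices; events
   on/after the index date never contribute.
4. **Selection** (`aspredict.selection`) — chi-squared *stability screening*:
   each feature is tested cases-vs-control-set once per control set (100
   tests) and survives only if p < 0.01 in at least 90% (male stratum; 75%
   female) of them; survivors pass a logistic-regression Wald filter at
   p < 0.01; the retained binary matrix is mean-centred and reduced by PCA to
   the components explaining 80% of variance.
5. **Model** (`aspredict.model`) — one shallow decision tree (Gini, depth 3)
   per case-vs-control-set pairing on the component scores; the final model is
   the candidate with the highest mean F value (harmonic mean of sensitivity
   and PPV) across all 100 pairings.  Leaves carry stable ids and their
   training case fraction, which doubles as the ROC risk score.
6. **Evaluation** (`aspredict.evaluate`) — the six confusion-matrix metrics,
   prevalence-adjusted PPV/NPV via Bayes' rule, the "perfect model"
   comparator (a hypothetical 90%-sensitive, 90%-specific classifier applied
   to population totals), ROC/AUC, and population-level generalisability with
   and without the development participants.

## Worked example

Run the full pipeline on a small synthetic male stratum (120 cases, 1:10
matching — the full study conditions use 380 cases and 1:100):

```bash
aspredict run --stratum male --n-cases 120 --ratio 10 --seed 5 --out run/
```

which prints

```
run complete: run/
mean F (train) = 0.881, mean F (test) = 0.863, test AUC = 0.912
```

and writes per-stage artifacts (CSV + a SHA-256 manifest) under `run/`.  The
metrics table, `run/evaluation/metrics.csv`:

```
dataset,sensitivity,specificity,ppv,npv,accuracy,f_value
train,88.1,85.71,86.05,87.8,86.9,87.06
test,83.33,75.0,76.92,81.82,79.17,80.0
test_pooled,83.33,90.0,45.45,98.18,89.39,58.82
```

`train` and `test` are paired case-vs-first-control-set evaluations; in the
pooled 1:10 test cohort the same tree keeps its sensitivity but PPV falls
from 76.92% to 45.45% — the prevalence deflation this pipeline is built to
expose.  The pooled test confusion matrix
(`run/evaluation/confusion_test_pooled.txt`):

```
                       PREDICTED
                              AS      NON_AS
OBSERVED  AS                  30           6    83.33%
          NON_AS              36         324    90.00%
                          45.45%      98.18%    89.39%
```

The fitted tree is readable clinically, one row per leaf
(`run/model/leaf_report.csv`, component scores labelled A, B, C …):

```
leaf_id,label,path,n_train,case_fraction
M1,NON_AS,A <= -0.317 and D <= -0.191,15,0.4
...
M7,AS,A > -0.317 and E > -0.705 and A > 0.017,52,0.9807692307692307
```

The same drop, pushed all the way to a ~0.09%-prevalence population, is
closed-form: a tree with the pooled test operating point (sensitivity 83.33%,
specificity 90.00%) would have

```python
>>> from aspredict.evaluate import prevalence_adjusted
>>> ppv, npv, flagged = prevalence_adjusted(0.8333, 0.90, 0.0009)
>>> round(100 * ppv, 2)
0.75
```

a PPV of 0.75% — and even a hypothetical 90%-sensitive, 90%-specific
"perfect model" applied to a male population with 2 102 AS cases among
1 296 522 people reaches only 1.44% PPV while flagging 10.1% of the
population.

Every stage is also a subcommand (`aspredict synth`, `cohort`, `features`,
`predict`, `evaluate`) reading and writing the documented CSV dialects, so
stages can be run and inspected independently.

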