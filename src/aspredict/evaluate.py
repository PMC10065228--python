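"""Confusion-matrix metrics, ROC/AUC, and prevalence-aware evaluation.

A classifier tuned on a 1:100 case-enriched cohort loses most of its positive
predictive value in a general population where the condition's prevalence is
~0.09%: PPV depends on prevalence through Bayes' rule while sensitivity and
specificity do not.  This module computes the six standard metrics from 2x2
counts (real-valued counts are allowed, for expected matrices), the
closed-form prevalence-adjusted PPV/NPV, the "perfect model" comparator (a
hypothetical 90%-sensitive, 90%-specific classifier applied to population
totals), and empirical ROC curves whose trapezoid AUC equals the rank-based
Mann-Whitney statistic.

The "F value" used for model selection is the harmonic mean of sensitivity
and positive predictive value (the F1 score).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

AS, NON_AS = "AS", "NON_AS"


def round2(x: float | None) -> float | None:
    """Half-up rounding to 2 decimal places, matching report formatting."""
    if x is None:
        return None
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 OBSERVED x PREDICTED counts; reals permitted (expected counts)."""

    tp: float
    fn: float
    fp: float
    tn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def observed_positive(self) -> float:
        return self.tp + self.fn

    @property
    def observed_negative(self) -> float:
        return self.fp + self.tn

    @property
    def predicted_positive(self) -> float:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricsReport:
    """The six derived metrics, as percentages on the 0-100 scale.

    A metric whose denominator is zero is ``None`` (undefined), never 0.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    f_value: float | None

    def rounded(self) -> "MetricsReport":
        return MetricsReport(*(round2(v) for v in (
            self.sensitivity, self.specificity, self.ppv, self.npv,
            self.accuracy, self.f_value)))

    def as_dict(self) -> dict[str, float | None]:
        return {"sensitivity": self.sensitivity, "specificity": self.specificity,
                "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
                "f_value": self.f_value}


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def f_value(tp: float, fn: float, fp: float, tn: float) -> float:
    """F value as a fraction in [0, 1]; 0 when sensitivity + PPV is 0 or when
    either is undefined (no observed or no predicted positives)."""
    sens = _ratio(tp, tp + fn)
    ppv = _ratio(tp, tp + fp)
    if sens is None or ppv is None or sens + ppv == 0:
        return 0.0
    return 2 * sens * ppv / (sens + ppv)


def confusion(predicted, observed) -> ConfusionMatrix:
    """Exact 2x2 cross-tabulation of AS / NON_AS label vectors."""
    predicted = np.asarray(predicted)
    observed = np.asarray(observed)
    if predicted.shape != observed.shape:
        raise ValueError("label vectors must have equal length")
    bad = set(np.unique(predicted)) | set(np.unique(observed))
    bad -= {AS, NON_AS}
    if bad:
        raise ValueError(f"labels outside {{AS, NON_AS}}: {sorted(bad)}")
    return ConfusionMatrix(
        tp=float(((predicted == AS) & (observed == AS)).sum()),
        fn=float(((predicted == NON_AS) & (observed == AS)).sum()),
        fp=float(((predicted == AS) & (observed == NON_AS)).sum()),
        tn=float(((predicted == NON_AS) & (observed == NON_AS)).sum()))


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """sens = tp/(tp+fn), spec = tn/(tn+fp), ppv = tp/(tp+fp),
    npv = tn/(tn+fn), accuracy = (tp+tn)/total, f = 2*sens*ppv/(sens+ppv),
    all x100."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    acc = (cm.tp + cm.tn) / cm.total
    if sens is None or ppv is None:
        f = None
    elif sens + ppv == 0:
        f = 0.0
    else:
        f = 2 * sens * ppv / (sens + ppv)
    pct = lambda v: None if v is None else 100.0 * v
    return MetricsReport(pct(sens), pct(spec), pct(ppv), pct(npv),
                         pct(acc), pct(f))


# ---------------------------------------------------------------------------
# prevalence adjustment and the perfect-model comparator
# ---------------------------------------------------------------------------

def prevalence_adjusted(sens: float, spec: float,
                        prevalence: float) -> tuple[float, float, float]:
    """Bayes-rule PPV, NPV and flagged fraction at a given prevalence.

    ppv = sens*pi / (sens*pi + (1-spec)(1-pi));
    flagged_fraction = sens*pi + (1-spec)(1-pi) (share of the population the
    model labels positive); npv analogous.  All arguments and results are
    fractions in (0, 1).
    """
    for name, v in (("sens", sens), ("spec", spec)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must be in (0, 1], got {v}")
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"degenerate prevalence {prevalence}: must be in (0, 1)")
    flagged = sens * prevalence + (1 - spec) * (1 - prevalence)
    ppv = sens * prevalence / flagged
    neg = (1 - sens) * prevalence + spec * (1 - prevalence)
    npv = spec * (1 - prevalence) / neg
    return ppv, npv, flagged


@dataclass(frozen=True)
class PerfectModelSpec:
    """Hypothetical upper-bound comparator: 90% sensitivity and specificity
    (higher would likely indicate overfitting)."""

    sensitivity: float = 0.90
    specificity: float = 0.90

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity):
            if not 0.0 < v <= 1.0:
                raise ValueError("sensitivity/specificity must be in (0, 1]")


def perfect_model(cm_population: ConfusionMatrix,
                  spec: PerfectModelSpec | None = None
                  ) -> tuple[ConfusionMatrix, MetricsReport]:
    """Expected confusion matrix of the comparator applied to the observed
    population totals: tp = sens * observed AS, tn = spec * observed NON_AS,
    remainders to fn / fp.  Counts are expectations, hence real-valued."""
    spec = spec or PerfectModelSpec()
    pos = cm_population.observed_positive
    neg = cm_population.observed_negative
    cm = ConfusionMatrix(tp=spec.sensitivity * pos,
                         fn=(1 - spec.sensitivity) * pos,
                         tn=spec.specificity * neg,
                         fp=(1 - spec.specificity) * neg)
    return cm, metrics(cm)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """Empirical ROC by threshold sweep over the distinct score values
    (predict positive when score >= threshold) and trapezoid AUC.  Tied
    scores move along the curve together, so the AUC equals the rank-based
    Mann-Whitney statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == AS
    neg = labels == NON_AS
    if not pos.any() or not neg.any():
        raise ValueError("ROC undefined: labels contain a single class")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    tp = np.cumsum(pos[order])
    fp = np.cumsum(neg[order])
    # keep the last index of each tied score block
    last = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[last] / pos.sum()]
    fpr = np.r_[0.0, fp[last] / neg.sum()]
    thresholds = np.r_[np.inf, s[last]]
    auc = float(np.trapezoid(tpr, fpr))
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return curve, auc


# ---------------------------------------------------------------------------
# generalisability
# ---------------------------------------------------------------------------

def generalize(predicted: pd.Series, observed: pd.Series,
               exclude_ids) -> dict[str, tuple[ConfusionMatrix, MetricsReport]]:
    """Population-level evaluation, with and without the model-development
    participants.

    Both series are indexed by unit/patient id.  ``all`` evaluates everyone;
    ``excluded`` drops ``exclude_ids`` (the training + testing participants)
    from the *observed-positive* arm only when they are cases — in the
    population tables the developed-case rows shrink while the control rows
    are unchanged, because development controls are a negligible, excluded-
    by-construction slice of the population frame passed in.
    """
    predicted, observed = predicted.align(observed, join="inner")
    cm_all = confusion(predicted.to_numpy(), observed.to_numpy())
    keep = ~predicted.index.isin(list(exclude_ids))
    cm_ex = confusion(predicted.to_numpy()[keep], observed.to_numpy()[keep])
    return {"all": (cm_all, metrics(cm_all)),
            "excluded": (cm_ex, metrics(cm_ex))}


# ---------------------------------------------------------------------------
# report formatting
# ---------------------------------------------------------------------------

def format_confusion(cm: ConfusionMatrix) -> str:
    """Aligned plain-text OBSERVED x PREDICTED table with row/column rates."""
    rep = metrics(cm).rounded()
    fmt = lambda v: f"{v:.0f}" if float(v).is_integer() else f"{v:.2f}"
    pc = lambda v: "-" if v is None else f"{v:.2f}%"
    lines = [
        f"{'':10s}{'':10s}{'PREDICTED':>12s}",
        f"{'':10s}{'':10s}{'AS':>12s}{'NON_AS':>12s}",
        f"{'OBSERVED':10s}{'AS':10s}{fmt(cm.tp):>12s}{fmt(cm.fn):>12s}"
        f"{pc(rep.sensitivity):>10s}",
        f"{'':10s}{'NON_AS':10s}{fmt(cm.fp):>12s}{fmt(cm.tn):>12s}"
        f"{pc(rep.specificity):>10s}",
        f"{'':20s}{pc(rep.ppv):>12s}{pc(rep.npv):>12s}{pc(rep.accuracy):>10s}",
    ]
    return "\n".join(lines)


def metrics_frame(rows: dict[str, MetricsReport]) -> pd.DataFrame:
    """Stack labelled metric reports into the six-column layout used by the
    training/testing/validation summary tables."""
    return pd.DataFrame({name: rep.rounded().as_dict()
                         for name, rep in rows.items()}).T[
        ["sensitivity", "specificity", "ppv", "npv", "accuracy", "f_value"]]
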