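"""Diagnostic-accuracy estimation for a binary rule-out test.

Builds 2x2 confusion counts from verified nodules and computes sensitivity,
specificity, predictive values, accuracy, prevalence and call rates with the
interval methods standard in diagnostic-accuracy reporting:

* exact Clopper-Pearson intervals (beta-quantile form) for binomial
  proportions — sensitivity, specificity, accuracy, prevalence;
* standard-logit (Mercaldo) intervals for PPV and NPV, parameterised by
  sensitivity (n1 diseased), specificity (n0 benign) and a fixed prevalence;
* Student-t intervals for means of continuous covariates.

Predictive values computed from a single 2x2 table's own crude sensitivity,
specificity and prevalence coincide algebraically with the crude tp/(tp+fp)
and tn/(tn+fn); the logit parameterisation matters when prevalence or
sensitivity comes from outside the table (verification-bias adjustment).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import Bethesda, NoduleRecord, TestResult, TruthLabel, truth_label


class Provenance(str, Enum):
    verified_only = "verified_only"
    mixed_extrapolated = "mixed_extrapolated"


class CIMethod(str, Enum):
    clopper_pearson = "clopper_pearson"
    logit_predictive = "logit_predictive"
    bayes_formula = "bayes_formula"
    crude = "crude"


class Sidedness(str, Enum):
    two_sided = "two_sided"
    lower_one_sided = "lower_one_sided"
    upper_one_sided = "upper_one_sided"


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 cell counts; provenance flags whether extrapolated cells are mixed in."""

    tp: int
    fp: int
    tn: int
    fn: int
    provenance: Provenance = Provenance.verified_only

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_benign(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ProportionEstimate:
    """Point estimate of a proportion with its confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    level: float
    method: CIMethod
    sided: Sidedness = Sidedness.two_sided
    x: float | None = None
    n: float | None = None

    def as_percent(self, digits: int = 1) -> tuple[float, float, float]:
        """(point, low, high) on the percent scale, half-up rounded."""
        return tuple(_round_half_up(100 * v, digits)
                     for v in (self.point, self.ci_low, self.ci_high))

    def to_dict(self) -> dict:
        return {
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "method": self.method.value,
            "sided": self.sided.value,
            "x": self.x,
            "n": self.n,
        }


def _round_half_up(value: float, digits: int = 1) -> float:
    scale = 10 ** digits
    return math.floor(value * scale + 0.5) / scale


def build_confusion(analyzable: Sequence[NoduleRecord]) -> ConfusionCounts:
    """Cross-tabulate test result against the histological truth label.

    Every record must carry a verified histology; pass the output of
    ``select_performance_set`` here.
    """
    tp = fp = tn = fn = 0
    for r in analyzable:
        label = truth_label(r)
        if label is TruthLabel.unknown:
            raise ValueError(
                f"nodule {r.nodule_id} has no verified histology; "
                "apply select_performance_set before building confusion counts"
            )
        if r.test_result not in (TestResult.negative, TestResult.positive):
            raise ValueError(f"nodule {r.nodule_id} was not tested")
        positive = r.test_result is TestResult.positive
        malignant = label is TruthLabel.malignant
        if positive and malignant:
            tp += 1
        elif positive:
            fp += 1
        elif malignant:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn,
                           provenance=Provenance.verified_only)


def clopper_pearson(
    x: int,
    n: int,
    level: float = 0.95,
    sided: Sidedness | str = Sidedness.two_sided,
) -> ProportionEstimate:
    """Exact (Clopper-Pearson) binomial confidence interval.

    Two-sided bounds are beta quantiles: lower = Beta(x, n-x+1) at alpha/2,
    upper = Beta(x+1, n-x) at 1-alpha/2, with the conventions lower=0 at x=0
    and upper=1 at x=n. One-sided variants spend all of alpha on the open
    side and pin the closed side at 0 or 1.
    """
    sided = Sidedness(sided)
    if n <= 0:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("x must satisfy 0 <= x <= n")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1 - level
    if sided is Sidedness.two_sided:
        a_lo = a_hi = alpha / 2
    elif sided is Sidedness.lower_one_sided:
        a_lo, a_hi = alpha, None
    else:
        a_lo, a_hi = None, alpha

    low = 0.0
    if a_lo is not None and x > 0:
        low = float(stats.beta.ppf(a_lo, x, n - x + 1))
    high = 1.0
    if a_hi is not None and x < n:
        high = float(stats.beta.ppf(1 - a_hi, x + 1, n - x))
    return ProportionEstimate(
        point=x / n, ci_low=low, ci_high=high, level=level,
        method=CIMethod.clopper_pearson, sided=sided, x=x, n=n,
    )


def ppv_from_rates(se: float, sp: float, prev: float) -> float:
    """Positive predictive value from sensitivity, specificity, prevalence."""
    return se * prev / (se * prev + (1 - sp) * (1 - prev))


def npv_from_rates(se: float, sp: float, prev: float) -> float:
    """Negative predictive value from sensitivity, specificity, prevalence."""
    return sp * (1 - prev) / ((1 - se) * prev + sp * (1 - prev))


def logit_predictive_ci(
    se: float,
    sp: float,
    prev: float,
    n1: int,
    n0: int,
    which: str,
    level: float = 0.95,
) -> ProportionEstimate:
    """Standard-logit (Mercaldo) confidence interval for PPV or NPV.

    The point estimate plugs se, sp and prev into Bayes' rule; the interval
    is the inverse-logit of ``logit(point) +/- z * sqrt(V)`` with the delta-
    method variance from the binomial errors of se (on n1 diseased) and sp
    (on n0 benign). Prevalence is treated as fixed and contributes no
    variance — appropriate when it is set externally rather than estimated
    from the same table.
    """
    if which not in ("ppv", "npv"):
        raise ValueError("which must be 'ppv' or 'npv'")
    if not (0 < se < 1 and 0 < sp < 1):
        raise ValueError(
            "degenerate sensitivity or specificity (0 or 1): the logit "
            "variance is undefined; use clopper_pearson on the crude "
            "predictive proportion instead"
        )
    if not 0 < prev < 1:
        raise ValueError("prevalence must be in (0, 1)")
    if min(n1, n0) < 1:
        raise ValueError("n1 and n0 must be >= 1")

    if which == "ppv":
        point = ppv_from_rates(se, sp, prev)
        var = (1 - se) / (se * n1) + sp / ((1 - sp) * n0)
    else:
        point = npv_from_rates(se, sp, prev)
        var = se / ((1 - se) * n1) + (1 - sp) / (sp * n0)
    z = float(stats.norm.ppf(1 - (1 - level) / 2))
    logit = math.log(point / (1 - point))
    half = z * math.sqrt(var)
    low = 1 / (1 + math.exp(-(logit - half)))
    high = 1 / (1 + math.exp(-(logit + half)))
    return ProportionEstimate(
        point=point, ci_low=low, ci_high=high, level=level,
        method=CIMethod.logit_predictive, sided=Sidedness.two_sided,
    )


@dataclass
class PerformanceReport:
    """Full accuracy panel for one 2x2 table; metrics may be None when undefined."""

    counts: ConfusionCounts
    level: float
    sensitivity: ProportionEstimate | None = None
    specificity: ProportionEstimate | None = None
    ppv: ProportionEstimate | None = None
    npv: ProportionEstimate | None = None
    accuracy: ProportionEstimate | None = None
    prevalence: ProportionEstimate | None = None
    benign_call_rate: ProportionEstimate | None = None
    positive_call_rate: ProportionEstimate | None = None
    per_bethesda: dict[str, "PerformanceReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d: dict = {
            "counts": {
                "tp": self.counts.tp, "fp": self.counts.fp,
                "tn": self.counts.tn, "fn": self.counts.fn,
                "provenance": self.counts.provenance.value,
            },
            "level": self.level,
        }
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy",
                     "prevalence", "benign_call_rate", "positive_call_rate"):
            est = getattr(self, name)
            d[name] = est.to_dict() if est is not None else None
        if self.per_bethesda:
            d["per_bethesda"] = {k: v.to_dict() for k, v in self.per_bethesda.items()}
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _predictive_estimate(which: str, counts: ConfusionCounts,
                         level: float) -> ProportionEstimate | None:
    """PPV/NPV with logit CI, falling back to exact CI on the crude proportion
    when sensitivity or specificity is degenerate (0 or 1)."""
    c = counts
    if which == "ppv":
        num, den = c.tp, c.tp + c.fp
    else:
        num, den = c.tn, c.tn + c.fn
    if den == 0:
        return None
    if c.n_diseased == 0 or c.n_benign == 0:
        return clopper_pearson(num, den, level)
    se = c.tp / c.n_diseased
    sp = c.tn / c.n_benign
    prev = c.n_diseased / c.total
    if se in (0.0, 1.0) or sp in (0.0, 1.0):
        return clopper_pearson(num, den, level)
    return logit_predictive_ci(se, sp, prev, c.n_diseased, c.n_benign,
                               which, level)


def performance_report(counts: ConfusionCounts, level: float = 0.95) -> PerformanceReport:
    """Compute the full accuracy panel for one confusion table.

    Sensitivity, specificity, prevalence and accuracy get exact intervals;
    PPV/NPV get standard-logit intervals fed by the table's own crude rates.
    Accuracy is reported only for fully verified tables: cells extrapolated
    from an external sensitivity do not correspond to observed agreement.
    A zero denominator leaves that single metric as None.
    """
    c = counts
    if c.total < 1:
        raise ValueError("empty confusion table")
    rep = PerformanceReport(counts=c, level=level)
    if c.n_diseased > 0:
        rep.sensitivity = clopper_pearson(c.tp, c.n_diseased, level)
    if c.n_benign > 0:
        rep.specificity = clopper_pearson(c.tn, c.n_benign, level)
    if c.provenance is Provenance.verified_only:
        rep.accuracy = clopper_pearson(c.tp + c.tn, c.total, level)
    rep.prevalence = clopper_pearson(c.n_diseased, c.total, level)
    rep.ppv = _predictive_estimate("ppv", c, level)
    rep.npv = _predictive_estimate("npv", c, level)
    n_neg = c.tn + c.fn
    n_pos = c.tp + c.fp
    rep.benign_call_rate = clopper_pearson(n_neg, c.total, level)
    rep.positive_call_rate = clopper_pearson(n_pos, c.total, level)
    return rep


def stratify_by_bethesda(
    analyzable: Sequence[NoduleRecord], level: float = 0.95
) -> dict[str, PerformanceReport]:
    """Per-Bethesda-class performance reports. Empty strata are omitted."""
    out: dict[str, PerformanceReport] = {}
    for cls in (Bethesda.III, Bethesda.IV):
        stratum = [r for r in analyzable if r.bethesda_class is cls]
        if not stratum:
            warnings.warn(f"empty Bethesda {cls.value} stratum; omitted")
            continue
        out[cls.value] = performance_report(build_confusion(stratum), level)
    return out


def mean_ci(values: Iterable[float], level: float = 0.95) -> tuple[float, float, float]:
    """Sample mean with a symmetric Student-t interval, mean +/- t * sd/sqrt(n)."""
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("mean_ci requires at least 2 values")
    m = float(arr.mean())
    sem = float(arr.std(ddof=1)) / math.sqrt(n)
    t = float(stats.t.ppf(1 - (1 - level) / 2, df=n - 1))
    return m, m - t * sem, m + t * sem


__all__ = [
    "Provenance", "CIMethod", "Sidedness",
    "ConfusionCounts", "ProportionEstimate", "PerformanceReport",
    "build_confusion", "clopper_pearson", "logit_predictive_ci",
    "ppv_from_rates", "npv_from_rates", "performance_report",
    "stratify_by_bethesda", "mean_ci",
]
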