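"""Partial-verification-bias adjustment by external-sensitivity extrapolation.

In a rule-out setting almost no test-negative patient is referred to surgery,
so the verified 2x2 table contains too few test-negative nodules to estimate
sensitivity or NPV (both appear to be 100%). The adjustment splits the pool
of unverified test-negative nodules into expected true and false negatives by
applying a sensitivity observed in an external validation study, and rebuilds
the confusion table with these extrapolated cells.

Three scenarios are supported:

* ``base_case`` — verified cells kept, the unverified negatives extrapolated
  and added to the verified tn/fn;
* ``scenario_1`` — the verified negatives discarded, only the extrapolated
  unverified negatives analysed;
* ``scenario_2`` — all test-negative nodules (verified and unverified)
  extrapolated, ignoring the surgical outcomes of the verified negatives.

The companion ``bayes_npv``/``bayes_ppv`` give the predictive values implied
by Bayes' theorem for arbitrary sensitivity/specificity/prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .performance import (
    ConfusionCounts,
    PerformanceReport,
    Provenance,
    npv_from_rates,
    performance_report,
    ppv_from_rates,
)


class Scenario(str, Enum):
    base_case = "base_case"
    scenario_1 = "scenario_1"
    scenario_2 = "scenario_2"


@dataclass(frozen=True)
class AdjustmentInput:
    """Verified table plus the unverified-negative pool and external sensitivity."""

    verified: ConfusionCounts
    n_unverified_negatives: int
    external_sensitivity: float

    def __post_init__(self):
        if self.n_unverified_negatives < 0:
            raise ValueError("n_unverified_negatives must be >= 0")
        if not 0 < self.external_sensitivity <= 1:
            raise ValueError("external_sensitivity must be in (0, 1]")


def extrapolate_negatives(
    n: int, s_ext: float, integer: bool = True
) -> tuple[float, float]:
    """Split n test-negative nodules into expected (true negatives, false negatives).

    tn = n * s_ext rounded half-up to an integer (the default, matching how
    published counts are reported); fn = n - tn, so the pool size is conserved
    exactly. With ``integer=False`` the fractional expectation is returned,
    useful in simulation work.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0 < s_ext <= 1:
        raise ValueError("s_ext must be in (0, 1]")
    tn = n * s_ext
    if integer:
        tn = math.floor(tn + 0.5)
    return tn, n - tn


def adjusted_confusion(
    inp: AdjustmentInput, scenario: Scenario | str = Scenario.base_case
) -> ConfusionCounts:
    """Confusion table with extrapolated negative cells for one scenario.

    tp/fp always come from the verified table (every test-positive analyzed
    nodule is verified); only the negative column differs between scenarios.
    """
    scenario = Scenario(scenario)
    v = inp.verified
    if scenario is Scenario.base_case:
        tn_x, fn_x = extrapolate_negatives(inp.n_unverified_negatives,
                                           inp.external_sensitivity)
        tn, fn = v.tn + tn_x, v.fn + fn_x
    elif scenario is Scenario.scenario_1:
        tn, fn = extrapolate_negatives(inp.n_unverified_negatives,
                                       inp.external_sensitivity)
    else:  # scenario_2: extrapolate the full negative pool
        n_all = inp.n_unverified_negatives + v.tn + v.fn
        tn, fn = extrapolate_negatives(n_all, inp.external_sensitivity)
    return ConfusionCounts(tp=v.tp, fp=v.fp, tn=int(tn), fn=int(fn),
                           provenance=Provenance.mixed_extrapolated)


def bayes_npv(se: float, sp: float, prev: float) -> float:
    """NPV from Bayes' theorem: sp(1-prev) / ((1-se)prev + sp(1-prev))."""
    _check_open_unit(se, sp, prev)
    return npv_from_rates(se, sp, prev)


def bayes_ppv(se: float, sp: float, prev: float) -> float:
    """PPV from Bayes' theorem: se*prev / (se*prev + (1-sp)(1-prev))."""
    _check_open_unit(se, sp, prev)
    return ppv_from_rates(se, sp, prev)


def _check_open_unit(*args: float) -> None:
    for a in args:
        if not 0 < a < 1:
            raise ValueError("sensitivity, specificity and prevalence must be in (0, 1)")


@dataclass(frozen=True)
class ScenarioResult:
    scenario_id: Scenario
    counts: ConfusionCounts
    report: PerformanceReport

    def to_dict(self) -> dict:
        return {"scenario_id": self.scenario_id.value, **self.report.to_dict()}


def run_scenarios(inp: AdjustmentInput, level: float = 0.95) -> list[ScenarioResult]:
    """Adjusted confusion + full performance report for all three scenarios."""
    out = []
    for scenario in (Scenario.base_case, Scenario.scenario_1, Scenario.scenario_2):
        counts = adjusted_confusion(inp, scenario)
        out.append(ScenarioResult(scenario, counts, performance_report(counts, level)))
    return out


__all__ = [
    "Scenario", "AdjustmentInput", "ScenarioResult",
    "extrapolate_negatives", "adjusted_confusion",
    "bayes_npv", "bayes_ppv", "run_scenarios",
]
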