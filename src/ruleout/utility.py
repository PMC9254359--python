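"""Clinical-utility metrics: surgery avoidance and decision support.

For a rule-out test, the clinical payoff is surgeries not performed. These
metrics assume the counterfactual that, without molecular testing, every
eligible indeterminate nodule proceeds to diagnostic surgery except those
whose positive-tested owners declined surgery anyway (they reveal they would
not have operated regardless of the result).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .cohort import NoduleRecord, TestResult
from .performance import ProportionEstimate, clopper_pearson


class AvoidanceMode(str, Enum):
    #: presumed-benign pool taken as printed in the source report (280)
    as_printed = "as_printed"
    #: pool recomputed from the flow-chart boxes (verified TN + unoperated
    #: negatives + false positives)
    recomputed = "recomputed"


def avoided_all(
    eligible_n: int,
    test_positive_unoperated: int,
    test_negative_unoperated: int,
    level: float = 0.95,
) -> ProportionEstimate:
    """Fraction of all counterfactual surgeries avoided.

    Denominator: eligible nodules minus positive-tested patients who declined
    surgery (assumed to decline under the counterfactual too). Numerator:
    negative-tested nodules managed without surgery.
    """
    den = eligible_n - test_positive_unoperated
    if den <= 0:
        raise ValueError("counterfactual surgery pool is empty")
    if test_negative_unoperated > den:
        raise ValueError("avoided count exceeds the counterfactual pool")
    return clopper_pearson(test_negative_unoperated, den, level)

def avoided_unnecessary(
    presumed_benign_pool: int,
    extrapolated_fn: int,
    benign_operated: int,
    level: float = 0.95,
) -> ProportionEstimate:
    """Fraction of 'potentially unnecessary' (benign-nodule) surgeries avoided.

    The presumed-benign pool is discounted by the false negatives expected
    among unoperated negatives; of the remainder, those actually operated
    (verified true negatives + false positives) were not avoided.
    """
    pool = presumed_benign_pool - extrapolated_fn
    if pool <= 0:
        raise ValueError("presumed-benign pool is empty after discounting")
    if benign_operated > pool:
        raise ValueError("operated benign count exceeds the pool")
    return clopper_pearson(pool - benign_operated, pool, level)


def decision_support(
    eligible: Sequence[NoduleRecord], level: float = 0.95
) -> tuple[ProportionEstimate, ProportionEstimate, ProportionEstimate]:
    """Concordance of management with the test result.

    Returns (negative-support, positive-support, overall): a negative result
    supports the decision when no surgery followed; a positive result when
    surgery followed.
    """
    negatives = [r for r in eligible if r.test_result is TestResult.negative]
    positives = [r for r in eligible if r.test_result is TestResult.positive]
    if len(negatives) + len(positives) != len(eligible):
        raise ValueError("all eligible records must carry a test result")
    neg_support = sum(1 for r in negatives if not r.surgery)
    pos_support = sum(1 for r in positives if r.surgery)
    neg = clopper_pearson(neg_support, len(negatives), level) if negatives else None
    pos = clopper_pearson(pos_support, len(positives), level) if positives else None
    overall = clopper_pearson(neg_support + pos_support, len(eligible), level)
    return neg, pos, overall


def surgeries_per_cancer(resected_positive: int, true_positive: int) -> float:
    """Surgeries performed per cancer found among test positives (1/PPV)."""
    if true_positive < 1:
        raise ValueError("true_positive must be >= 1")
    if resected_positive < true_positive:
        raise ValueError("resected_positive must be >= true_positive")
    return resected_positive / true_positive


def surgeries_per_cancer_from_ppv(ppv: float) -> float:
    """Surgeries per cancer implied by a (possibly external) PPV."""
    if not 0 < ppv <= 1:
        raise ValueError("ppv must be in (0, 1]")
    return 1 / ppv


def comparison_table(table: pd.DataFrame) -> pd.DataFrame:
    """Surgeries-per-cancer comparison across tests from a PPV table.

    Expects columns ``test`` and ``ppv`` (proportions); returns the table
    with a ``surgeries_per_cancer`` column appended. PPVs quoted as
    percentages (values > 1) are rescaled.
    """
    if not {"test", "ppv"} <= set(table.columns):
        raise ValueError("comparison table needs 'test' and 'ppv' columns")
    out = table.copy()
    ppv = out["ppv"].astype(float)
    ppv = ppv.where(ppv <= 1, ppv / 100)
    out["surgeries_per_cancer"] = 1 / ppv
    return out


@dataclass
class UtilityMetrics:
    """Bundle of the utility panel for one analysed cohort."""

    avoided_all_surgeries: ProportionEstimate
    avoided_unnecessary_surgeries: ProportionEstimate
    avoidance_mode: AvoidanceMode
    decision_support_negative: ProportionEstimate | None
    decision_support_positive: ProportionEstimate | None
    decision_support_overall: ProportionEstimate
    surgeries_per_cancer: float

    def to_dict(self) -> dict:
        def opt(est):
            return est.to_dict() if est is not None else None

        return {
            "avoided_all_surgeries": opt(self.avoided_all_surgeries),
            "avoided_unnecessary_surgeries": opt(self.avoided_unnecessary_surgeries),
            "avoidance_mode": self.avoidance_mode.value,
            "decision_support_negative": opt(self.decision_support_negative),
            "decision_support_positive": opt(self.decision_support_positive),
            "decision_support_overall": opt(self.decision_support_overall),
            "surgeries_per_cancer": self.surgeries_per_cancer,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


__all__ = [
    "AvoidanceMode", "UtilityMetrics",
    "avoided_all", "avoided_unnecessary", "decision_support",
    "surgeries_per_cancer", "surgeries_per_cancer_from_ppv", "comparison_table",
]
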