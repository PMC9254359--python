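"""End-to-end analysis driver and plain-text report rendering.

``run_analysis`` ties the pipeline together: eligibility flow, performance
set, verified and adjusted confusion tables, scenario sensitivity analyses,
Bethesda stratification and the clinical-utility panel, all serialised into
one deterministic metrics dictionary. ``render_report`` turns that dictionary
into a human-readable markdown summary (exclusion-flow box list plus a
performance table per scenario).
"""

from __future__ import annotations

import json
from typing import Sequence

from .adjustment import AdjustmentInput, run_scenarios
from .cohort import NoduleRecord, TestResult, apply_eligibility_flow, select_performance_set
from .performance import build_confusion, performance_report, stratify_by_bethesda
from .utility import (
    AvoidanceMode,
    UtilityMetrics,
    avoided_all,
    avoided_unnecessary,
    decision_support,
    surgeries_per_cancer,
)


def run_analysis(
    records: Sequence[NoduleRecord],
    s_ext: float,
    level: float = 0.95,
    mode: AvoidanceMode | str = AvoidanceMode.as_printed,
    as_printed_pool: int = 280,
) -> dict:
    """Run the full clinical-performance and utility analysis.

    Parameters
    ----------
    records
        Raw cohort (pre-eligibility).
    s_ext
        External sensitivity used to extrapolate unverified test negatives.
        Must be given explicitly; there is no silent default.
    level
        Confidence level for all intervals.
    mode
        Presumed-benign pool for the avoided-unnecessary-surgeries rate:
        ``as_printed`` uses the externally stated pool size
        (``as_printed_pool``); ``recomputed`` rebuilds the pool from the
        cohort's own flow counts. Both figures are included in the output,
        ``mode`` selects which one is headlined.
    """
    mode = AvoidanceMode(mode)
    eligible, eligibility_audit = apply_eligibility_flow(records)
    analyzable, performance_audit = select_performance_set(eligible)
    if not analyzable:
        raise ValueError("no analyzable nodules after the eligibility flow")

    verified = build_confusion(analyzable)
    verified_report = performance_report(verified, level)
    per_bethesda = stratify_by_bethesda(analyzable, level)

    analyzable_ids = {r.nodule_id for r in analyzable}
    negatives = [r for r in eligible if r.test_result is TestResult.negative]
    positives = [r for r in eligible if r.test_result is TestResult.positive]
    neg_unoperated = sum(1 for r in negatives if not r.surgery)
    pos_unoperated = sum(1 for r in positives if not r.surgery)
    n_unverified_neg = sum(1 for r in negatives if r.nodule_id not in analyzable_ids)

    adj_input = AdjustmentInput(verified, n_unverified_neg, s_ext)
    scenarios = run_scenarios(adj_input, level)
    base = scenarios[0]

    fn_star = base.counts.fn - verified.fn
    benign_operated = verified.tn + verified.fp
    pools = {
        AvoidanceMode.as_printed: as_printed_pool,
        AvoidanceMode.recomputed: verified.tn + neg_unoperated + verified.fp,
    }
    avoided_unnecessary_by_mode = {
        m.value: avoided_unnecessary(pool, fn_star, benign_operated, level)
        for m, pool in pools.items()
    }
    ds_neg, ds_pos, ds_all = decision_support(eligible, level)
    resected_positive = sum(
        1 for r in analyzable if r.test_result is TestResult.positive
    )
    utility = UtilityMetrics(
        avoided_all_surgeries=avoided_all(
            len(eligible), pos_unoperated, neg_unoperated, level),
        avoided_unnecessary_surgeries=avoided_unnecessary_by_mode[mode.value],
        avoidance_mode=mode,
        decision_support_negative=ds_neg,
        decision_support_positive=ds_pos,
        decision_support_overall=ds_all,
        surgeries_per_cancer=surgeries_per_cancer(resected_positive, verified.tp),
    )

    return {
        "level": level,
        "s_ext": s_ext,
        "eligibility_audit": eligibility_audit.to_dict(),
        "performance_audit": performance_audit.to_dict(),
        "verified": verified_report.to_dict(),
        "per_bethesda": {k: v.to_dict() for k, v in per_bethesda.items()},
        "scenarios": [s.to_dict() for s in scenarios],
        "utility": {
            **utility.to_dict(),
            "avoided_unnecessary_by_mode": {
                k: v.to_dict() for k, v in avoided_unnecessary_by_mode.items()
            },
        },
    }


def _pct(est: dict | None, digits: int = 1) -> str:
    if est is None:
        return "-"
    point = 100 * est["point"]
    lo, hi = 100 * est["ci_low"], 100 * est["ci_high"]
    return f"{point:.{digits}f}% ({lo:.{digits}f}-{hi:.{digits}f})"


def _render_performance_table(title: str, rep: dict, lines: list[str]) -> None:
    c = rep["counts"]
    lines.append(f"### {title}")
    lines.append("")
    lines.append(f"2x2 table ({c['provenance']}): "
                 f"TP={c['tp']} FP={c['fp']} TN={c['tn']} FN={c['fn']}")
    lines.append("")
    lines.append("| metric | estimate (CI) |")
    lines.append("|---|---|")
    for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy",
                 "prevalence", "benign_call_rate", "positive_call_rate"):
        lines.append(f"| {name} | {_pct(rep.get(name))} |")
    lines.append("")


def render_report(metrics: dict) -> str:
    """Render an analysis metrics dictionary as a markdown report."""
    lines: list[str] = ["# Rule-out classifier analysis report", ""]

    lines.append("## Exclusion flow")
    lines.append("")
    for audit_key, label in (("eligibility_audit", "cohort eligibility"),
                             ("performance_audit", "performance set")):
        audit = metrics[audit_key]
        lines.append(f"- {label}: start {audit['initial_count']}")
        for step in audit["steps"]:
            detail = step.get("detail")
            extra = f" ({json.dumps(detail, sort_keys=True)})" if detail else ""
            lines.append(
                f"  - {step['step_name']}: excluded {step['excluded_count']}"
                f"{extra}, remaining {step['remaining_count']}"
            )
    lines.append("")

    _render_performance_table("Verified nodules", metrics["verified"], lines)
    for cls, rep in metrics.get("per_bethesda", {}).items():
        _render_performance_table(f"Bethesda {cls}", rep, lines)
    for scen in metrics.get("scenarios", []):
        _render_performance_table(f"Adjusted: {scen['scenario_id']}", scen, lines)

    util = metrics.get("utility")
    if util:
        lines.append("## Clinical utility")
        lines.append("")
        lines.append("| metric | estimate (CI) |")
        lines.append("|---|---|")
        for name in ("avoided_all_surgeries", "avoided_unnecessary_surgeries",
                     "decision_support_negative", "decision_support_positive",
                     "decision_support_overall"):
            lines.append(f"| {name} | {_pct(util.get(name))} |")
        lines.append(f"| surgeries_per_cancer | {util['surgeries_per_cancer']:.2f} |")
        lines.append(f"| avoidance_mode | {util['avoidance_mode']} |")
        lines.append("")
    return "\n".join(lines)


__all__ = ["run_analysis", "render_report"]
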