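"""Accuracy metrics and confidence-interval machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from statsmodels.stats.proportion import proportion_confint

from ruleout import (
    Bethesda,
    ConfusionCounts,
    Histology,
    TestResult,
    build_confusion,
    clopper_pearson,
    logit_predictive_ci,
    mean_ci,
    performance_report,
    stratify_by_bethesda,
)
from ruleout.performance import CIMethod, Provenance, Sidedness
from ruleout.simulate import SimulationParams, simulate_cohort

from test_cohort import make_record


def binomial_tail_cp(x, n, level=0.95):
    """Independent exact-interval oracle: bisection over binomial tails
    computed by direct summation of the pmf (no beta quantiles)."""
    alpha = 1 - level

    def sf_at_least(x0, p):  # P(X >= x0)
        return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(x0, n + 1))

    def cdf_at_most(x0, p):  # P(X <= x0)
        return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(0, x0 + 1))

    low = 0.0 if x == 0 else brentq(
        lambda p: sf_at_least(x, p) - alpha / 2, 1e-15, 1 - 1e-15, xtol=1e-13)
    high = 1.0 if x == n else brentq(
        lambda p: cdf_at_most(x, p) - alpha / 2, 1e-15, 1 - 1e-15, xtol=1e-13)
    return low, high


class TestClopperPearson:
    def test_one_sided_bound_for_17_of_17(self):
        est = clopper_pearson(17, 17, level=0.975, sided=Sidedness.lower_one_sided)
        assert est.point == 1.0
        assert est.ci_high == 1.0
        assert round(est.ci_low, 3) == 0.805

    def test_boundary_conventions(self):
        assert clopper_pearson(0, 10).ci_low == 0.0
        assert clopper_pearson(10, 10).ci_high == 1.0

    @pytest.mark.parametrize("x,n", [(100, 112), (17, 168), (3, 7), (0, 5), (5, 5)])
    def test_matches_binomial_tail_bisection_oracle(self, x, n):
        est = clopper_pearson(x, n)
        low, high = binomial_tail_cp(x, n)
        assert est.ci_low == pytest.approx(low, abs=1e-9)
        assert est.ci_high == pytest.approx(high, abs=1e-9)

    @pytest.mark.parametrize("x,n", [(0, 1), (7, 30), (100, 112), (222, 423)])
    def test_agrees_with_statsmodels_beta_interval(self, x, n):
        est = clopper_pearson(x, n)
        lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
        assert est.ci_low == pytest.approx(float(lo), abs=1e-12)
        assert est.ci_high == pytest.approx(float(hi), abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(n=st.integers(1, 200), data=st.data(),
           level=st.sampled_from([0.9, 0.95, 0.99]))
    def test_interval_nesting_and_containment(self, n, data, level):
        x = data.draw(st.integers(0, n))
        wide = clopper_pearson(x, n, level=0.99)
        narrow = clopper_pearson(x, n, level=0.90)
        est = clopper_pearson(x, n, level=level)
        assert wide.ci_low <= narrow.ci_low <= narrow.ci_high <= wide.ci_high
        assert est.ci_low <= est.point <= est.ci_high

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)
        with pytest.raises(ValueError):
            clopper_pearson(5, 3)


class TestLogitPredictiveCI:
    SE, SP, PREV = 100 / 112, 227 / 278, 112 / 390

    def test_reproduces_ppv_point_and_interval(self):
        est = logit_predictive_ci(self.SE, self.SP, self.PREV, 112, 278, "ppv")
        assert round(est.point, 3) == 0.662
        assert round(est.ci_low, 3) == 0.603
        assert round(est.ci_high, 3) == 0.717

    def test_reproduces_npv_point_and_interval(self):
        est = logit_predictive_ci(self.SE, self.SP, self.PREV, 112, 278, "npv")
        assert round(est.point, 3) == 0.950
        assert round(est.ci_low, 3) == 0.917
        assert round(est.ci_high, 3) == 0.970

    def test_symmetric_inputs_give_half(self):
        est = logit_predictive_ci(0.5, 0.5, 0.5, 10, 10, "ppv")
        assert est.point == pytest.approx(0.5, abs=1e-12)

    def test_crude_identity_with_table_rates(self):
        # fed a table's own se/sp/prev, the PPV point is exactly tp/(tp+fp)
        tp, fp, tn, fn = 37, 22, 61, 9
        se, sp = tp / (tp + fn), tn / (tn + fp)
        prev = (tp + fn) / (tp + fp + tn + fn)
        est = logit_predictive_ci(se, sp, prev, tp + fn, tn + fp, "ppv")
        assert est.point == pytest.approx(tp / (tp + fp), abs=1e-12)
        est_n = logit_predictive_ci(se, sp, prev, tp + fn, tn + fp, "npv")
        assert est_n.point == pytest.approx(tn / (tn + fn), abs=1e-12)

    def test_npv_monotone_in_specificity_and_prevalence(self):
        base = logit_predictive_ci(0.9, 0.8, 0.3, 50, 50, "npv").point
        assert logit_predictive_ci(0.9, 0.85, 0.3, 50, 50, "npv").point > base
        assert logit_predictive_ci(0.9, 0.8, 0.35, 50, 50, "npv").point < base

    def test_degenerate_rates_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="clopper_pearson"):
            logit_predictive_ci(1.0, 0.8, 0.3, 50, 50, "npv")


class TestBuildConfusion:
    def test_reference_counts(self, verified_counts):
        c = verified_counts
        assert (c.tp, c.fp, c.tn, c.fn) == (100, 51, 17, 0)
        assert c.provenance is Provenance.verified_only

    def test_empty_input(self):
        c = build_confusion([])
        assert c.total == 0

    def test_one_record_per_cell(self):
        mk = lambda i, test, hist: make_record(
            i, test_result=test, surgery=True, ap_report_available=True,
            fna_ap_concordant=True, histology=hist)
        records = [
            mk(1, TestResult.positive, Histology.ptc_usual),
            mk(2, TestResult.positive, Histology.colloid_goitre),
            mk(3, TestResult.negative, Histology.colloid_goitre),
            mk(4, TestResult.negative, Histology.ptc_usual),
        ]
        c = build_confusion(records)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)

    def test_unverified_record_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="select_performance_set"):
            build_confusion([make_record()])


class TestPerformanceReport:
    def test_adjusted_base_case_panel(self):
        counts = ConfusionCounts(100, 51, 227, 12,
                                 provenance=Provenance.mixed_extrapolated)
        rep = performance_report(counts)
        assert rep.sensitivity.as_percent()[0] == 89.3
        assert round(100 * rep.specificity.point, 2) == 81.65
        assert rep.ppv.as_percent()[0] == 66.2
        assert rep.npv.as_percent()[0] == 95.0
        assert rep.prevalence.as_percent()[0] == 28.7
        assert rep.accuracy is None  # extrapolated cells: no observed agreement

    def test_verified_accuracy_70_percent(self, verified_counts):
        rep = performance_report(verified_counts)
        assert round(100 * rep.accuracy.point) == 70
        # degenerate sensitivity (fn=0): predictive values fall back to exact
        assert rep.npv.method is CIMethod.clopper_pearson
        assert round(rep.npv.ci_low, 3) == 0.805

    def test_symmetric_table(self):
        rep = performance_report(ConfusionCounts(25, 25, 25, 25))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy",
                     "prevalence"):
            assert getattr(rep, name).point == 0.5

    def test_call_rates_sum_to_one(self, verified_counts):
        rep = performance_report(verified_counts)
        assert rep.benign_call_rate.point + rep.positive_call_rate.point == 1.0

    def test_zero_denominator_flags_single_metric(self):
        rep = performance_report(ConfusionCounts(0, 3, 7, 0))
        assert rep.sensitivity is None
        assert rep.specificity is not None
        assert rep.prevalence.point == 0.0

    def test_json_serialisation_fields(self, verified_counts):
        d = performance_report(verified_counts).to_dict()
        assert set(d["sensitivity"]) == {
            "point", "ci_low", "ci_high", "level", "method", "sided", "x", "n"}


class TestStratification:
    def test_reference_per_class_ppv(self, analyzable):
        strata = stratify_by_bethesda(analyzable)
        assert strata["III"].ppv.as_percent()[0] == 62.7
        assert strata["IV"].ppv.as_percent()[0] == 70.6

    def test_single_class_equals_unstratified(self, analyzable):
        third = [r for r in analyzable if r.bethesda_class is Bethesda.III]
        with pytest.warns(UserWarning, match="Bethesda IV"):
            strata = stratify_by_bethesda(third)
        assert list(strata) == ["III"]
        assert strata["III"].counts == build_confusion(third)

    def test_strata_cells_sum_to_unstratified(self):
        params = SimulationParams(n_nodules=400, p_surgery_given_negative=1.0,
                                  p_surgery_given_positive=1.0,
                                  p_lost_followup=0.0,
                                  p_ap_missing_given_surgery=0.0,
                                  p_discordant_given_ap=0.0, seed=5)
        records, _ = simulate_cohort(params)
        total = build_confusion(records)
        strata = stratify_by_bethesda(records)
        for cell in ("tp", "fp", "tn", "fn"):
            assert sum(getattr(s.counts, cell) for s in strata.values()) == \
                getattr(total, cell)


class TestMeanCI:
    def test_constant_sample_has_zero_width(self):
        m, lo, hi = mean_ci([1, 1, 1, 1])
        assert (m, lo, hi) == (1.0, 1.0, 1.0)

    def test_two_point_sample_symmetric(self):
        m, lo, hi = mean_ci([0, 10])
        assert m == 5.0
        assert hi - m == pytest.approx(m - lo)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            mean_ci([3.0])

    def test_monte_carlo_coverage(self):
        # t-interval should cover the true mean ~95% of the time
        rng = np.random.default_rng(2024)
        mu, reps, n = 3.0, 2000, 30
        hits = 0
        for _ in range(reps):
            sample = rng.normal(mu, 2.0, size=n)
            _, lo, hi = mean_ci(sample)
            hits += lo <= mu <= hi
        assert abs(hits / reps - 0.95) < 0.02
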