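# ruleout

Clinical-performance and clinical-utility analysis of **rule-out molecular
classifiers** applied to cytologically indeterminate (Bethesda III/IV)
thyroid nodules.

In real-world practice, most patients with a negative ("benign") molecular
result avoid diagnostic surgery — which is exactly the test's purpose, but it
means the reference standard (post-surgical histology) is observed almost
only for test-positive nodules. Naively computed sensitivity and NPV are then
badly distorted by **partial verification bias**. This package implements,
as a tested and reusable pipeline, the analysis chain used to evaluate such
a test from routine follow-up data:

- **Cohort model and eligibility flow** — a nodule-level data model
  (cytology class, test result, follow-up, surgery, pathology-report
  availability and concordance, final histology), CSV I/O with validation,
  and the exclusion flow with a conserving audit trail.
- **Diagnostic accuracy** — 2×2 confusion tables; sensitivity, specificity,
  accuracy and prevalence with exact *Clopper–Pearson* intervals; PPV and
  NPV via Bayes' rule with *standard-logit (Mercaldo)* intervals
  parameterised by Se (on n₁ diseased), Sp (on n₀ benign) and a fixed
  prevalence:

  PPV = Se·p / (Se·p + (1−Sp)(1−p)),  NPV = Sp(1−p) / ((1−Se)p + Sp(1−p)),

  with Var(logit PPV) = (1−Se)/(Se·n₁) + Sp/((1−Sp)·n₀) and
  Var(logit NPV) = Se/((1−Se)·n₁) + (1−Sp)/(Sp·n₀).
- **Verification-bias adjustment** — the unverified test-negative pool is
  split into expected true/false negatives by an externally validated
  sensitivity (tn★ = round(N·s_ext), fn★ = N − tn★) and the confusion table
  rebuilt; three scenarios (keep, drop, or replace the few verified
  negatives) quantify how much the conclusion depends on that choice.
- **Clinical utility** — avoided-surgery rates (all and "potentially
  unnecessary"), decision-support rates, and surgeries-per-cancer-detected
  (1/PPV).
- **Synthetic cohorts** — a generative model of the testing pathway with
  known ground truth (including disease-dependent referral, which creates
  genuine verification bias), plus a deterministic 488-nodule reference
  cohort reproducing every published marginal of the motivating real-world
  study.

## Worked example

```python
import ruleout as ro

records = ro.study_cohort()                      # 488 nodules
eligible, audit = ro.apply_eligibility_flow(records)
analyzable, _ = ro.select_performance_set(eligible)
verified = ro.build_confusion(analyzable)
print(len(eligible), len(analyzable), verified)

adjusted = ro.adjusted_confusion(
    ro.AdjustmentInput(verified, n_unverified_negatives=222,
                       external_sensitivity=0.946))
rep = ro.performance_report(adjusted)
print("Se", rep.sensitivity.as_percent())
print("NPV", rep.npv.as_percent())
print("avoided", ro.avoided_all(440, 17, 222).as_percent())
```

prints

```
440 168 ConfusionCounts(tp=100, fp=51, tn=17, fn=0, provenance=<Provenance.verified_only: 'verified_only'>)
Se (89.3, 82.0, 94.3)
NPV (95.0, 91.7, 97.0)
avoided (52.5, 47.6, 57.3)
```

i.e. of 488 consented nodules, 440 are eligible and 168 have verified
histology; the verified table shows 100 true and 51 false positives with all
17 resected negatives benign. After extrapolating the 222 unverified
negatives at the externally validated 94.6% sensitivity, the test shows
89.3% sensitivity (95% CI 82.0–94.3) and 95.0% NPV (91.7–97.0), and 52.5%
(47.6–57.3) of counterfactual surgeries were avoided.

The same analysis from the shell:

```bash
ruleout analyze --fixture --s-ext 0.946 --out out/
ruleout report --metrics out/metrics.json
ruleout simulate --n 1000 --seed 7 --out sim/   # synthetic cohort + truth
```

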