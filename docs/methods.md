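# Methods

## Setting and unit of analysis

The package analyses the clinical performance of a binary rule-out molecular
classifier applied to thyroid nodules with indeterminate fine-needle
aspiration cytology (Bethesda III/IV). The unit of analysis is the nodule:
patients may contribute more than one nodule, and patient-level figures are
derived views over nodule records. Post-surgical anatomopathological (AP)
histology is the reference standard; NIFTP is counted as malignant because
its diagnosis itself requires resection, so a positive call on a NIFTP is a
true positive for the decision the test supports.

## Eligibility flow

Exclusions are applied in a fixed order: (1) loss to follow-up, (2) cytology
outside Bethesda III/IV; the performance set then restricts to resected
nodules, drops those without a retrievable original AP report, and drops
those whose AP report cannot be matched to the punctured nodule. A record
violating several criteria is charged to the first matching step, so step
counts are order-dependent but always conserve the total (checked by a
property test). The audit is emitted as JSON and log lines so a run can be
diffed against a published flow chart box by box.

## Interval estimation

* **Binomial proportions** (sensitivity, specificity, accuracy, prevalence,
  call rates, utility rates): exact Clopper–Pearson intervals in the
  beta-quantile form, lower = Beta(x, n−x+1) at α/2 and upper = Beta(x+1,
  n−x) at 1−α/2, with lower = 0 at x = 0 and upper = 1 at x = n. One-sided
  variants spend the whole α on the open side (used for the 17/17 verified
  negatives, whose 97.5% one-sided lower bound is 0.805). The implementation
  uses scipy's beta quantiles; the test suite checks it exhaustively against
  an independent bisection over exact binomial tail sums for all n ≤ 50, and
  against statsmodels' `proportion_confint(method="beta")`.
* **Predictive values**: points from Bayes' rule; intervals on the logit
  scale with the delta-method variance contributed by Se (n₁ diseased) and
  Sp (n₀ benign). Prevalence is treated as fixed with no variance
  contribution — the parameterisation appropriate when prevalence is set
  externally, and the one that reproduces the published bounds when applied
  to the adjusted table (PPV 60.3–71.7, NPV 91.7–97.0). When Se or Sp is
  degenerate (0 or 1) the logit variance is undefined; the report then falls
  back to a Clopper–Pearson interval on the crude predictive proportion,
  signalled in the method tag, never silently. Fed a single table's own
  crude Se/Sp/prevalence, the predictive-value points reduce algebraically
  to tp/(tp+fp) and tn/(tn+fn) (asserted to 1e-12).
* **Means** of continuous covariates: symmetric Student-t intervals,
  mean ± t(1−α/2, n−1)·sd/√n, coverage-checked by Monte Carlo.
* The normal and t quantiles are computed exactly, never hard-coded; display
  rounding is half-up at one decimal on the percent scale, with full
  precision retained internally.

## Verification-bias adjustment

Let N be the unverified test-negative pool and s_ext a sensitivity observed
in an external validation study. The adjustment splits the pool as
tn★ = round-half-up(N·s_ext), fn★ = N − tn★, conserving N exactly; a
fractional (no-rounding) mode exists for simulation work but integer counts
are the default, matching how such tables are published. Multiplying the
negative pool by a sensitivity is arithmetically an NPV-style extrapolation;
the package reproduces that published arithmetic as-is and exposes
`bayes_npv`/`bayes_ppv` separately for the exact Bayes-rule quantities,
without conflating the two. Three scenarios bound the dependence on the few
verified negatives: `base_case` adds the extrapolated cells to the verified
ones; `scenario_1` discards the verified negatives; `scenario_2`
extrapolates the entire negative pool, ignoring the verified negatives'
surgical outcomes. Accuracy is reported only for fully verified tables —
extrapolated cells do not correspond to observed agreement.

## Clinical utility

The counterfactual is that, absent molecular testing, every eligible
indeterminate nodule proceeds to diagnostic surgery except those whose
positive-tested owners declined surgery anyway. Avoided-all = unoperated
negatives over that pool. For avoided-unnecessary surgeries the
presumed-benign pool is discounted by the extrapolated false negatives; two
pool definitions are provided because the motivating study's stated pool
(280) does not equal the sum of its own components (17 + 222 + 51 = 290):
`as_printed` (default, reproduces the published 200/268 = 74.6%) and
`recomputed` (210/278 = 75.5%). Both figures appear in every analysis
output; the mode only selects which is headlined. The published CI for the
74.6% rate (69–79.2) is narrower at the top than the Clopper–Pearson
interval on 200/268 (69.0–79.7); the method behind the printed bound is
unstated, and this package reports its own exact interval.
Surgeries-per-cancer is resected positives over true positives, i.e. 1/PPV
on the crude scale; a helper converts external PPVs for cross-test
comparison tables.

## Synthetic cohorts

`simulate_cohort` draws, per nodule and in fixed field order from one seeded
generator: latent disease state (prevalence), Bethesda class, test result
(true sensitivity/specificity), loss to follow-up, surgery referral
conditional on the test result, AP-report availability and concordance, and
a histological subtype from per-truth-class weight tables. Defaults are the
study conditions of the motivating cohort: prevalence 0.287, sensitivity
0.946, specificity 0.82, surgery in 91.5% of positives and 7.1% of
negatives, 8% loss to follow-up, 12.4% missing and 4.5% discordant reports,
and subtype weights estimated from the verified cells (100 malignant, 68
benign). An odds multiplier (`disease_referral_odds`, default 1) lets
referral additionally depend on the latent disease state, producing genuine
non-ignorable verification; time-to-surgery and follow-up delays are
gamma-shaped plumbing with no claim of distributional fidelity. The
generator emulates the management pathway, not biology: it has no
ultrasound features, no repeat-FNA history, no within-patient correlation,
and referral depends only on test result and disease state — so passing
tests demonstrate correctness of the estimators under the assumed pathway,
not robustness to every real-world selection mechanism.

`study_cohort` is a deterministic 488-record cohort reproducing every
published marginal of the motivating study (flow box counts; test-by-
Bethesda margins; all verified histology cells; sex, age-band and lobe
margins per test result; the size bands of the 168 analyzable nodules; 481
patients overall and 435 among the 440 eligible nodules, with the five
two-nodule patients in the published mix). Quantities not pinned by any
published margin are filled deterministically: the 25 missing-report
positives are assigned Bethesda III and the 8 discordant ones Bethesda IV —
the only simple assignment consistent with both the test-by-Bethesda margins
and the analyzable totals — and ages are 40/60 representatives of the
published age bands.

`verification_bias_demo` runs the full pipeline on one simulated cohort and
returns (naive NPV from resected negatives only, extrapolation-adjusted NPV,
true NPV from the ground truth). Under disease-dependent referral the naive
estimate is biased downward and the adjusted one should land closer to the
truth; the test suite checks this in ≥ 95% of 200 replicates at n = 4000
with a referral odds multiplier of 8, and checks parameter recovery
(sensitivity/specificity within 3 binomial standard errors) on a fully
verified cohort of n = 50,000. These sizes keep the whole suite fast while
leaving Monte-Carlo error well inside the asserted tolerances.

## Numerical conventions and degenerate inputs

Empty strata are omitted with a warning rather than raising; a zero
denominator leaves that single metric undefined (None) while the rest of the
panel is computed; empty cohorts flow through the eligibility functions as
empty outputs with zero-count audits, but building a performance report of
an empty table is an error. Cohort CSVs accept empty fields or `NA` as
missing on read and write empty fields; files are written sorted by nodule
id so equal cohorts serialise byte-identically, and all analysis outputs are
deterministic (sorted JSON keys, no timestamps).

## Design choices

Plain dataclasses with explicit validation (rather than a schema library)
keep the data model dependency-light and transparent; enums are closed — an
unrecognised histology or Bethesda label is a validation error, never a
silent mapping. The external sensitivity used for extrapolation must always
be passed explicitly, in the API and the CLI; there is no silent default,
because the adjusted NPV is only as credible as that borrowed number. The
command-line layer is a thin wrapper over the library (`simulate`,
`analyze`, `report`), with YAML config files overridden by flags.

## Known limitations

The adjustment inherits the transportability assumption that the external
sensitivity applies to the unverified pool; the scenarios probe the verified
negatives' influence but not that assumption itself. Confidence intervals
for scenario tables treat extrapolated counts as ordinary binomial counts,
understating uncertainty in s_ext. The published CI bounds of the scenario
sensitivity analysis used an unavailable method and are deliberately not
reproduced; this package reports its own intervals for those tables.
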