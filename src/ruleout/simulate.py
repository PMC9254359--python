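"""Synthetic nodule cohorts with known ground truth.

Two generators live here:

* :func:`simulate_cohort` draws stochastic cohorts from a generative model of
  the real-world testing pathway — latent disease state, a binary test with
  configurable sensitivity/specificity, surgery referral conditional on the
  test result (optionally also on the latent disease state, which creates
  genuine partial-verification bias), loss to follow-up, missing or
  discordant pathology reports, and histological subtypes drawn per truth
  class. The ground truth is returned alongside, so estimators can be checked
  against the parameters that generated the data.

* :func:`study_cohort` emits a deterministic 488-record reference cohort
  whose every marginal matches the published real-world study this package
  analyses: the exclusion-flow box counts, the test-by-Bethesda margins, and
  all per-subtype histology cells of the verified 2x2 table.

:func:`verification_bias_demo` runs the full analysis pipeline on a simulated
cohort and contrasts the naive (resected-only) NPV, the extrapolation-
adjusted NPV, and the generator's true NPV among test negatives.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .adjustment import AdjustmentInput, Scenario, adjusted_confusion
from .cohort import (
    Bethesda,
    Histology,
    Lobe,
    NoduleRecord,
    Sex,
    TestResult,
    apply_eligibility_flow,
    select_performance_set,
)
from .performance import build_confusion, performance_report

#: Default histology subtype frequencies, estimated from the verified cells of
#: the reference cohort (100 malignant, 68 benign).
DEFAULT_MALIGNANT_WEIGHTS: dict[Histology, float] = {
    Histology.ptc_usual: 0.30,
    Histology.ptc_follicular_variant: 0.46,
    Histology.ptc_hurthle_variant: 0.03,
    Histology.niftp: 0.09,
    Histology.fc_microinvasive: 0.09,
    Histology.fc_widely_invasive: 0.01,
    Histology.fc_hurthle_variant: 0.01,
    Histology.medullary: 0.01,
}
DEFAULT_BENIGN_WEIGHTS: dict[Histology, float] = {
    Histology.hurthle_adenoma: 11 / 68,
    Histology.follicular_adenoma: 25 / 68,
    Histology.adenomatous_goitre: 16 / 68,
    Histology.colloid_goitre: 13 / 68,
    Histology.hashimoto: 3 / 68,
}


@dataclass
class SimulationParams:
    """Generative parameters for a synthetic indeterminate-nodule cohort.

    Defaults reproduce the study conditions of the motivating real-world
    cohort: 28.7% malignancy prevalence among Bethesda III/IV nodules, a
    rule-out test with 94.6% sensitivity and 82% specificity, surgery in
    91.5% of positives but only 7.1% of negatives, 8% loss to follow-up,
    12.4% of surgical nodules without a retrievable pathology report and
    4.5% with a discordant one.
    """

    n_nodules: int = 440
    prevalence: float = 0.287
    p_bethesda_iii: float = 0.561
    sensitivity_true: float = 0.946
    specificity_true: float = 0.82
    p_surgery_given_positive: float = 0.915
    p_surgery_given_negative: float = 0.071
    p_lost_followup: float = 0.08
    p_ap_missing_given_surgery: float = 0.124
    p_discordant_given_ap: float = 0.045
    #: odds multiplier on surgery referral for truly malignant nodules;
    #: 1.0 = referral depends on the test result only, >1 creates
    #: disease-dependent (non-ignorable) verification.
    disease_referral_odds: float = 1.0
    malignant_weights: dict[Histology, float] = field(
        default_factory=lambda: dict(DEFAULT_MALIGNANT_WEIGHTS))
    benign_weights: dict[Histology, float] = field(
        default_factory=lambda: dict(DEFAULT_BENIGN_WEIGHTS))
    seed: int = 0

    def validate(self) -> None:
        props = {
            "prevalence": self.prevalence,
            "p_bethesda_iii": self.p_bethesda_iii,
            "sensitivity_true": self.sensitivity_true,
            "specificity_true": self.specificity_true,
            "p_surgery_given_positive": self.p_surgery_given_positive,
            "p_surgery_given_negative": self.p_surgery_given_negative,
            "p_lost_followup": self.p_lost_followup,
            "p_ap_missing_given_surgery": self.p_ap_missing_given_surgery,
            "p_discordant_given_ap": self.p_discordant_given_ap,
        }
        for name, v in props.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_nodules < 0:
            raise ValueError("n_nodules must be >= 0")
        if self.disease_referral_odds <= 0:
            raise ValueError("disease_referral_odds must be > 0")
        for label, weights, allowed in (
            ("malignant_weights", self.malignant_weights, None),
            ("benign_weights", self.benign_weights, None),
        ):
            total = sum(weights.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{label} must sum to 1 (got {total})")
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{label} must be non-negative")


@dataclass
class GroundTruth:
    """Latent disease state per nodule, plus the parameters that generated it."""

    seed: int
    diseased: dict[str, bool]
    params: dict

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {"seed": self.seed, "params": self.params, "diseased": self.diseased},
            **kwargs,
        )


def _params_to_jsonable(params: SimulationParams) -> dict:
    d = asdict(params)
    d["malignant_weights"] = {k.value: v for k, v in params.malignant_weights.items()}
    d["benign_weights"] = {k.value: v for k, v in params.benign_weights.items()}
    return d


def simulate_cohort(
    params: SimulationParams,
) -> tuple[list[NoduleRecord], GroundTruth]:
    """Draw one synthetic cohort; deterministic for a fixed seed.

    Per-nodule quantities are drawn in fixed field order (disease state,
    Bethesda class, test result, follow-up, surgery, report availability,
    concordance, histology, demographics) from a single seeded generator, so
    cohorts are bit-reproducible across runs and platforms.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_nodules

    diseased = rng.random(n) < params.prevalence
    beth_iii = rng.random(n) < params.p_bethesda_iii
    u_test = rng.random(n)
    positive = np.where(diseased, u_test < params.sensitivity_true,
                        u_test < 1 - params.specificity_true)
    followed = rng.random(n) >= params.p_lost_followup
    p_surg = np.where(positive, params.p_surgery_given_positive,
                      params.p_surgery_given_negative)
    o = params.disease_referral_odds
    if o != 1.0:
        boosted = o * p_surg / (1 - p_surg + o * p_surg)
        p_surg = np.where(diseased, boosted, p_surg)
    surgery = (rng.random(n) < p_surg) & followed
    ap_available = surgery & (rng.random(n) >= params.p_ap_missing_given_surgery)
    concordant = ap_available & (rng.random(n) >= params.p_discordant_given_ap)

    mal_labels = list(params.malignant_weights)
    mal_p = np.array([params.malignant_weights[h] for h in mal_labels])
    ben_labels = list(params.benign_weights)
    ben_p = np.array([params.benign_weights[h] for h in ben_labels])
    mal_idx = rng.choice(len(mal_labels), size=n, p=mal_p / mal_p.sum())
    ben_idx = rng.choice(len(ben_labels), size=n, p=ben_p / ben_p.sum())

    female = rng.random(n) < 0.82
    ages = rng.integers(18, 91, size=n)
    lobe_idx = rng.choice(3, size=n, p=[0.398, 0.536, 0.066])
    sizes = np.round(rng.lognormal(mean=math.log(1.4), sigma=0.45, size=n), 2)
    surg_days = np.maximum(1, rng.gamma(shape=2.0, scale=60.0, size=n)).astype(int)
    fup_days = np.maximum(1, rng.gamma(shape=4.0, scale=100.0, size=n)).astype(int)

    lobes = [Lobe.left, Lobe.right, Lobe.isthmus]
    records: list[NoduleRecord] = []
    truth: dict[str, bool] = {}
    width = max(4, len(str(n)))
    for i in range(n):
        nid = f"N{i + 1:0{width}d}"
        verified = bool(concordant[i])
        if verified:
            hist = mal_labels[mal_idx[i]] if diseased[i] else ben_labels[ben_idx[i]]
        else:
            hist = Histology.none
        rec = NoduleRecord(
            patient_id=f"P{i + 1:0{width}d}",
            nodule_id=nid,
            bethesda_class=Bethesda.III if beth_iii[i] else Bethesda.IV,
            test_result=TestResult.positive if positive[i] else TestResult.negative,
            sex=Sex.female if female[i] else Sex.male,
            age_years=int(ages[i]),
            followed_up=bool(followed[i]),
            surgery=bool(surgery[i]),
            ap_report_available=bool(ap_available[i]),
            fna_ap_concordant=bool(concordant[i]),
            histology=hist,
            nodule_size_cm=float(sizes[i]) if verified else None,
            lobe=lobes[lobe_idx[i]],
            test_to_surgery_days=int(surg_days[i]) if surgery[i] else None,
            follow_up_days=None if surgery[i] else int(fup_days[i]),
        )
        records.append(rec)
        truth[nid] = bool(diseased[i])
    gt = GroundTruth(seed=params.seed, diseased=truth,
                     params=_params_to_jsonable(params))
    return records, gt


def verification_bias_demo(
    params: SimulationParams,
) -> tuple[float, float, float]:
    """Contrast naive, adjusted and true NPV on one simulated cohort.

    Runs the full pipeline (eligibility flow, performance set, confusion
    table, base-case extrapolation using the generator's own sensitivity as
    the external value) and returns ``(naive_npv, adjusted_npv, true_npv)``:

    * naive — NPV among resected, verified test-negative nodules only;
    * adjusted — NPV of the extrapolation-adjusted table;
    * true — fraction of truly benign nodules among all eligible test
      negatives (from the ground truth).

    When surgery referral depends on the latent disease state
    (``disease_referral_odds > 1``), the naive NPV is biased downward and
    the adjusted NPV should land closer to the truth.
    """
    if params.p_surgery_given_negative >= params.p_surgery_given_positive:
        raise ValueError("demo requires rule-out referral: "
                         "p_surgery_given_negative < p_surgery_given_positive")
    records, gt = simulate_cohort(params)
    eligible, _ = apply_eligibility_flow(records)
    analyzable, _ = select_performance_set(eligible)
    verified = build_confusion(analyzable)

    negatives = [r for r in eligible if r.test_result is TestResult.negative]
    analyzable_ids = {r.nodule_id for r in analyzable}
    n_unverified = sum(1 for r in negatives if r.nodule_id not in analyzable_ids)

    if not negatives:
        return float("nan"), float("nan"), float("nan")
    true_npv = sum(1 for r in negatives if not gt.diseased[r.nodule_id]) / len(negatives)

    n_ver_neg = verified.tn + verified.fn
    naive_npv = verified.tn / n_ver_neg if n_ver_neg else float("nan")

    adj = adjusted_confusion(
        AdjustmentInput(verified, n_unverified, params.sensitivity_true),
        Scenario.base_case,
    )
    n_adj_neg = adj.tn + adj.fn
    adjusted_npv = adj.tn / n_adj_neg if n_adj_neg else float("nan")
    return naive_npv, adjusted_npv, true_npv


# ---------------------------------------------------------------------------
# Deterministic reference cohort


def _expand(pairs: Sequence[tuple[Histology, int]]) -> list[Histology]:
    out: list[Histology] = []
    for hist, count in pairs:
        out.extend([hist] * count)
    return out


# Verified histology cells, per Bethesda class, of the reference cohort.
_TN_III = _expand([(Histology.hurthle_adenoma, 2), (Histology.follicular_adenoma, 1),
                   (Histology.colloid_goitre, 5), (Histology.hashimoto, 1)])
_TN_IV = _expand([(Histology.hurthle_adenoma, 2), (Histology.follicular_adenoma, 3),
                  (Histology.adenomatous_goitre, 2), (Histology.colloid_goitre, 1)])
_TP_III = _expand([(Histology.ptc_usual, 23), (Histology.ptc_follicular_variant, 16),
                   (Histology.ptc_hurthle_variant, 2), (Histology.niftp, 6),
                   (Histology.fc_microinvasive, 4), (Histology.medullary, 1)])
_TP_IV = _expand([(Histology.ptc_usual, 7), (Histology.ptc_follicular_variant, 30),
                  (Histology.ptc_hurthle_variant, 1), (Histology.niftp, 3),
                  (Histology.fc_microinvasive, 5), (Histology.fc_widely_invasive, 1),
                  (Histology.fc_hurthle_variant, 1)])
_FP_III = _expand([(Histology.hurthle_adenoma, 4), (Histology.follicular_adenoma, 10),
                   (Histology.adenomatous_goitre, 9), (Histology.colloid_goitre, 6),
                   (Histology.hashimoto, 2)])
_FP_IV = _expand([(Histology.hurthle_adenoma, 3), (Histology.follicular_adenoma, 11),
                  (Histology.adenomatous_goitre, 5), (Histology.colloid_goitre, 1)])


class _Demographics:
    """Deterministic per-test-result filler matching the cohort-table margins."""

    def __init__(self, n_male: int, n_young: int, n_left: int, n_right: int):
        self.n_male, self.n_young = n_male, n_young
        self.n_left, self.n_right = n_left, n_right
        self.i = 0

    def next(self) -> tuple[Sex, int, Lobe]:
        i = self.i
        self.i += 1
        sex = Sex.male if i < self.n_male else Sex.female
        age = 40 if i < self.n_young else 60
        if i < self.n_left:
            lobe = Lobe.left
        elif i < self.n_left + self.n_right:
            lobe = Lobe.right
        else:
            lobe = Lobe.isthmus
        return sex, age, lobe


def _size_for(index: int, n_small: int, n_medium: int) -> float:
    if index < n_small:
        return 1.5
    if index < n_small + n_medium:
        return 2.5
    return 4.5


def study_cohort() -> list[NoduleRecord]:
    """Deterministic 488-record reference cohort.

    Reproduces every published marginal of the motivating study: 39 nodules
    lost to follow-up, 8 Bethesda V and 1 Bethesda II exclusions; 440
    eligible (247 III / 193 IV); 239 test negatives (17 resected — all
    benign, 9 III / 8 IV — and 222 unresected); 201 test positives (17
    unresected, 25 without a retrievable AP report, 8 with a discordant one,
    and 151 analyzable with the exact per-subtype, per-Bethesda histology
    cell counts: 100 malignant including 9 NIFTP and 1 medullary, 51
    benign). Sex, age-band and lobe margins per test result and the size
    bands of the 168 analyzable nodules match the cohort table; attributes
    not pinned by any published margin are filled deterministically.
    """
    records: list[NoduleRecord] = []
    neg_demo = _Demographics(n_male=50, n_young=124, n_left=83, n_right=139)
    pos_demo = _Demographics(n_male=29, n_young=128, n_left=92, n_right=97)
    neg_size_i = 0
    pos_size_i = 0

    def nid() -> str:
        return f"N{len(records) + 1:04d}"

    def add(**kwargs) -> None:
        records.append(NoduleRecord(patient_id="", nodule_id=nid(), **kwargs))

    # --- excluded blocks -------------------------------------------------
    for i in range(39):  # lost to follow-up
        add(bethesda_class=Bethesda.III if i % 2 == 0 else Bethesda.IV,
            test_result=TestResult.negative if i % 2 == 0 else TestResult.positive,
            followed_up=False)
    for _ in range(8):  # Bethesda V
        add(bethesda_class=Bethesda.V, test_result=TestResult.positive)
    add(bethesda_class=Bethesda.II, test_result=TestResult.negative)  # Bethesda II

    # --- eligible: test-negative ----------------------------------------
    def add_negative(bethesda: Bethesda, *, surgery: bool,
                     histology: Histology = Histology.none) -> None:
        nonlocal neg_size_i
        sex, age, lobe = neg_demo.next()
        size = None
        if surgery:
            size = _size_for(neg_size_i, 12, 4)
            neg_size_i += 1
        add(bethesda_class=bethesda, test_result=TestResult.negative,
            sex=sex, age_years=age, lobe=lobe, surgery=surgery,
            ap_report_available=surgery, fna_ap_concordant=surgery,
            histology=histology, nodule_size_cm=size,
            test_to_surgery_days=170 if surgery else None,
            follow_up_days=None if surgery else 413)

    for hist in _TN_III:
        add_negative(Bethesda.III, surgery=True, histology=hist)
    for hist in _TN_IV:
        add_negative(Bethesda.IV, surgery=True, histology=hist)
    for _ in range(117):
        add_negative(Bethesda.III, surgery=False)
    for _ in range(105):
        add_negative(Bethesda.IV, surgery=False)

    # --- eligible: test-positive ----------------------------------------
    def add_positive(bethesda: Bethesda, *, surgery: bool, ap: bool = False,
                     concordant: bool = False,
                     histology: Histology = Histology.none) -> None:
        nonlocal pos_size_i
        sex, age, lobe = pos_demo.next()
        size = None
        if surgery and ap and concordant:
            size = _size_for(pos_size_i, 133, 17)
            pos_size_i += 1
        add(bethesda_class=bethesda, test_result=TestResult.positive,
            sex=sex, age_years=age, lobe=lobe, surgery=surgery,
            ap_report_available=ap, fna_ap_concordant=concordant,
            histology=histology, nodule_size_cm=size,
            test_to_surgery_days=79 if surgery else None,
            follow_up_days=None if surgery else 360)

    for _ in range(13):
        add_positive(Bethesda.III, surgery=False)
    for _ in range(4):
        add_positive(Bethesda.IV, surgery=False)
    for _ in range(25):  # resected, AP report unavailable
        add_positive(Bethesda.III, surgery=True, ap=False)
    for _ in range(8):  # resected, AP report discordant with the FNA nodule
        add_positive(Bethesda.IV, surgery=True, ap=True, concordant=False)
    for hist in _TP_III + _FP_III:
        add_positive(Bethesda.III, surgery=True, ap=True, concordant=True,
                     histology=hist)
    for hist in _TP_IV + _FP_IV:
        add_positive(Bethesda.IV, surgery=True, ap=True, concordant=True,
                     histology=hist)

    assert len(records) == 488
    _assign_patients(records)
    for rec in records:
        rec.validate()
    return records


def _assign_patients(records: list[NoduleRecord]) -> None:
    """Assign patient ids: 435 patients over the 440 eligible nodules (five
    two-nodule patients: one both-negative, one both-positive, three mixed)
    and 46 over the 48 excluded (two two-nodule patients)."""
    by_id = {r.nodule_id: i for i, r in enumerate(records)}

    def idx(block_start: int, offset: int) -> int:
        return block_start + offset

    # block offsets in construction order
    lost0 = 0                      # 39 lost to follow-up
    neg_unres0 = 48 + 17           # after 48 excluded + 17 resected negatives
    pos_unres0 = 48 + 239          # first unresected positive
    pos_analyz0 = 48 + 239 + 17 + 25 + 8  # first analyzable positive

    pairs = [
        (idx(lost0, 0), idx(lost0, 1)),            # excluded pair 1
        (idx(lost0, 2), idx(lost0, 3)),            # excluded pair 2
        (idx(neg_unres0, 0), idx(neg_unres0, 1)),  # both nodules negative
        (idx(pos_analyz0, 0), idx(pos_analyz0, 1)),  # both nodules positive
        (idx(neg_unres0, 2), idx(pos_unres0, 0)),  # mixed
        (idx(neg_unres0, 3), idx(pos_unres0, 1)),  # mixed
        (idx(neg_unres0, 4), idx(pos_unres0, 2)),  # mixed
    ]
    partner: dict[int, int] = {}
    for a, b in pairs:
        partner[a], partner[b] = b, a

    next_pid = 1
    assigned: dict[int, str] = {}
    for i, rec in enumerate(records):
        if i in assigned:
            rec.patient_id = assigned[i]
            continue
        pid = f"P{next_pid:04d}"
        next_pid += 1
        rec.patient_id = pid
        if i in partner:
            assigned[partner[i]] = pid
    del by_id


__all__ = [
    "SimulationParams", "GroundTruth",
    "DEFAULT_MALIGNANT_WEIGHTS", "DEFAULT_BENIGN_WEIGHTS",
    "simulate_cohort", "study_cohort", "verification_bias_demo",
]
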