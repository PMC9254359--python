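"""Nodule-level cohort model, I/O and eligibility flow.

The unit of analysis is the biopsied nodule, not the patient: a cohort is a
list of :class:`NoduleRecord`, each carrying the cytology (Bethesda) class,
the binary molecular test result, the management path (follow-up, surgery,
availability and concordance of the post-surgical anatomopathological [AP]
report) and, for fully verified nodules, the final histology.

Eligibility mirrors the exclusion flow of a real-world rule-out study:
nodules lost to follow-up are removed first, then nodules whose cytology is
outside the indeterminate classes (Bethesda III/IV); the performance set is
further restricted to resected nodules with an available, FNA-concordant AP
report. Every step is recorded in an :class:`EligibilityAudit` so the flow
is diffable against the study's published box counts.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class Sex(str, Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class Bethesda(str, Enum):
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    other = "other"


class TestResult(str, Enum):
    negative = "negative"
    positive = "positive"
    not_tested = "not_tested"


class Lobe(str, Enum):
    left = "left"
    right = "right"
    isthmus = "isthmus"
    unknown = "unknown"


class Histology(str, Enum):
    ptc_usual = "ptc_usual"
    ptc_follicular_variant = "ptc_follicular_variant"
    ptc_hurthle_variant = "ptc_hurthle_variant"
    niftp = "niftp"
    fc_microinvasive = "fc_microinvasive"
    fc_widely_invasive = "fc_widely_invasive"
    fc_hurthle_variant = "fc_hurthle_variant"
    medullary = "medullary"
    hurthle_adenoma = "hurthle_adenoma"
    follicular_adenoma = "follicular_adenoma"
    adenomatous_goitre = "adenomatous_goitre"
    colloid_goitre = "colloid_goitre"
    hashimoto = "hashimoto"
    none = "none"


class TruthLabel(str, Enum):
    malignant = "malignant"
    benign = "benign"
    unknown = "unknown"


#: Histological subtypes counted as malignant. NIFTP is deliberately included:
#: although clinically indolent, its diagnosis requires resection, so for
#: test-performance purposes a positive call on a NIFTP is a true positive.
MALIGNANT_HISTOLOGIES = frozenset(
    {
        Histology.ptc_usual,
        Histology.ptc_follicular_variant,
        Histology.ptc_hurthle_variant,
        Histology.niftp,
        Histology.fc_microinvasive,
        Histology.fc_widely_invasive,
        Histology.fc_hurthle_variant,
        Histology.medullary,
    }
)

BENIGN_HISTOLOGIES = frozenset(
    {
        Histology.hurthle_adenoma,
        Histology.follicular_adenoma,
        Histology.adenomatous_goitre,
        Histology.colloid_goitre,
        Histology.hashimoto,
    }
)


class CohortValidationError(ValueError):
    """A cohort file or record violates the data model."""


@dataclass
class NoduleRecord:
    """One biopsied nodule: test result, management path, final histology."""

    patient_id: str
    nodule_id: str
    bethesda_class: Bethesda
    test_result: TestResult
    sex: Sex = Sex.unknown
    age_years: int | None = None
    followed_up: bool = True
    surgery: bool = False
    ap_report_available: bool = False
    fna_ap_concordant: bool = False
    histology: Histology = Histology.none
    nodule_size_cm: float | None = None
    lobe: Lobe = Lobe.unknown
    test_to_surgery_days: int | None = None
    follow_up_days: int | None = None

    def __post_init__(self):
        self.sex = Sex(self.sex)
        self.bethesda_class = Bethesda(self.bethesda_class)
        self.test_result = TestResult(self.test_result)
        self.histology = Histology(self.histology)
        self.lobe = Lobe(self.lobe)

    def validate(self) -> None:
        """Check single-record invariants; raise CohortValidationError."""
        verified = self.surgery and self.ap_report_available and self.fna_ap_concordant
        if (self.histology is not Histology.none) != verified:
            raise CohortValidationError(
                f"nodule {self.nodule_id}: histology must be set iff the nodule "
                "was resected with an available, concordant AP report"
            )
        if self.age_years is not None and self.age_years < 0:
            raise CohortValidationError(f"nodule {self.nodule_id}: negative age")
        if self.nodule_size_cm is not None and self.nodule_size_cm <= 0:
            raise CohortValidationError(f"nodule {self.nodule_id}: non-positive size")


def truth_label(record: NoduleRecord) -> TruthLabel:
    """Reference-standard disease state of a nodule.

    Malignant iff the AP histology is a carcinoma or NIFTP; benign for the
    benign subtypes; unknown when no verified histology exists (unresected,
    missing or discordant AP report).
    """
    if record.histology is Histology.none:
        return TruthLabel.unknown
    if record.histology in MALIGNANT_HISTOLOGIES:
        return TruthLabel.malignant
    return TruthLabel.benign


@dataclass
class AuditStep:
    step_name: str
    excluded_count: int
    remaining_count: int
    detail: dict[str, int] = field(default_factory=dict)


@dataclass
class EligibilityAudit:
    """Ordered record of exclusion steps, conserving counts at every step."""

    initial_count: int
    steps: list[AuditStep] = field(default_factory=list)

    def add(self, name: str, excluded: Sequence[NoduleRecord], remaining: int,
            detail: dict[str, int] | None = None) -> None:
        self.steps.append(
            AuditStep(name, len(excluded), remaining, dict(detail or {}))
        )

    @property
    def final_count(self) -> int:
        return self.steps[-1].remaining_count if self.steps else self.initial_count

    def to_dict(self) -> dict:
        return {
            "initial_count": self.initial_count,
            "final_count": self.final_count,
            "steps": [
                {
                    "step_name": s.step_name,
                    "excluded_count": s.excluded_count,
                    "remaining_count": s.remaining_count,
                    **({"detail": s.detail} if s.detail else {}),
                }
                for s in self.steps
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def apply_eligibility_flow(
    records: Sequence[NoduleRecord],
) -> tuple[list[NoduleRecord], EligibilityAudit]:
    """Apply the cohort-level exclusions, in fixed order.

    1. nodules lost to follow-up;
    2. nodules whose cytology is not Bethesda III/IV.

    A record failing both criteria is charged to the first step. Returns the
    eligible (followed-up, indeterminate-cytology) set and the audit.
    """
    audit = EligibilityAudit(initial_count=len(records))

    kept = [r for r in records if r.followed_up]
    lost = [r for r in records if not r.followed_up]
    audit.add("lost_to_follow_up", lost, len(kept))

    eligible = [r for r in kept if r.bethesda_class in (Bethesda.III, Bethesda.IV)]
    off_class = [r for r in kept if r.bethesda_class not in (Bethesda.III, Bethesda.IV)]
    by_class: dict[str, int] = {}
    for r in off_class:
        by_class[r.bethesda_class.value] = by_class.get(r.bethesda_class.value, 0) + 1
    audit.add("bethesda_not_iii_iv", off_class, len(eligible), by_class)
    return eligible, audit


def select_performance_set(
    eligible: Sequence[NoduleRecord],
) -> tuple[list[NoduleRecord], EligibilityAudit]:
    """Restrict the eligible set to nodules with verified histology.

    Drops, in order: unresected nodules; resected nodules without the original
    AP report; resected nodules whose AP report does not match the punctured
    nodule. The survivors all have a truth label.
    """
    audit = EligibilityAudit(initial_count=len(eligible))

    resected = [r for r in eligible if r.surgery]
    audit.add("not_resected", [r for r in eligible if not r.surgery], len(resected))

    with_ap = [r for r in resected if r.ap_report_available]
    audit.add(
        "ap_report_unavailable",
        [r for r in resected if not r.ap_report_available],
        len(with_ap),
    )

    analyzable = [r for r in with_ap if r.fna_ap_concordant]
    audit.add(
        "fna_ap_discordant",
        [r for r in with_ap if not r.fna_ap_concordant],
        len(analyzable),
    )
    return analyzable, audit


# ---------------------------------------------------------------------------
# Cohort file I/O

_COLUMNS = [f.name for f in fields(NoduleRecord)]
_MISSING_TOKENS = {"", "NA"}
_BOOL_COLUMNS = {"followed_up", "surgery", "ap_report_available", "fna_ap_concordant"}
_INT_COLUMNS = {"age_years", "test_to_surgery_days", "follow_up_days"}
_ENUM_COLUMNS = {
    "sex": Sex,
    "bethesda_class": Bethesda,
    "test_result": TestResult,
    "histology": Histology,
    "lobe": Lobe,
}


def _parse_cell(column: str, raw: str, row_num: int):
    if raw in _MISSING_TOKENS:
        if column in ("patient_id", "nodule_id"):
            raise CohortValidationError(f"row {row_num}, column {column}: missing identifier")
        if column in _BOOL_COLUMNS:
            return False
        if column in _ENUM_COLUMNS:
            defaults = {"sex": Sex.unknown, "lobe": Lobe.unknown, "histology": Histology.none}
            if column in defaults:
                return defaults[column]
            raise CohortValidationError(f"row {row_num}, column {column}: value required")
        return None
    try:
        if column in _BOOL_COLUMNS:
            low = raw.strip().lower()
            if low in ("true", "1"):
                return True
            if low in ("false", "0"):
                return False
            raise ValueError(raw)
        if column in _INT_COLUMNS:
            return int(raw)
        if column == "nodule_size_cm":
            return float(raw)
        if column in _ENUM_COLUMNS:
            return _ENUM_COLUMNS[column](raw.strip())
    except ValueError as exc:
        raise CohortValidationError(
            f"row {row_num}, column {column}: invalid value {raw!r}"
        ) from exc
    return raw


def read_cohort(path: str | Path, delimiter: str = ",") -> list[NoduleRecord]:
    """Read a cohort CSV (one nodule per row, header = field names).

    Empty fields and ``NA`` are treated as missing. Unknown enumeration values
    raise :class:`CohortValidationError` naming the row and column; duplicate
    nodule ids raise a cohort-level error.
    """
    path = Path(path)
    records: list[NoduleRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing_cols = [c for c in _COLUMNS if c not in header]
        if missing_cols:
            raise CohortValidationError(f"missing required columns: {missing_cols}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            kwargs = {c: _parse_cell(c, (row[c] or "").strip(), i) for c in _COLUMNS}
            rec = NoduleRecord(**kwargs)
            rec.validate()
            records.append(rec)
    seen: dict[str, int] = {}
    for r in records:
        seen[r.nodule_id] = seen.get(r.nodule_id, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise CohortValidationError(f"duplicate nodule_id values: {dupes}")
    return records


def write_cohort(records: Iterable[NoduleRecord], path: str | Path,
                 delimiter: str = ",") -> None:
    """Write a cohort CSV, sorted by nodule_id; missing values as empty."""
    path = Path(path)
    rows = sorted(records, key=lambda r: r.nodule_id)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_COLUMNS)
        for r in rows:
            out = []
            for c in _COLUMNS:
                v = getattr(r, c)
                if v is None:
                    out.append("")
                elif isinstance(v, Enum):
                    out.append(v.value)
                elif isinstance(v, bool):
                    out.append("true" if v else "false")
                else:
                    out.append(str(v))
            writer.writerow(out)


__all__ = [
    "Sex", "Bethesda", "TestResult", "Lobe", "Histology", "TruthLabel",
    "MALIGNANT_HISTOLOGIES", "BENIGN_HISTOLOGIES",
    "NoduleRecord", "AuditStep", "EligibilityAudit", "CohortValidationError",
    "truth_label", "apply_eligibility_flow", "select_performance_set",
    "read_cohort", "write_cohort", "replace",
]
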