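"""Breast-level label assignment and test-set eligibility rules.

Labels come from coded pathology findings dated near the ultrasound exam:
a breast is labeled malignant if any malignant finding falls within the
window from 30 days before to 120 days after the exam (benign analogously;
both labels may hold at once). Eligibility rules then decide whether a
record belongs in a clinically realistic test set:

* non-biopsied BI-RADS 1-2 breasts need a cancer-free 0-15 months and a
  BI-RADS 1-2 follow-up at 6-24 months;
* non-biopsied BI-RADS 3 breasts need a cancer-free 0-15 months and either
  all follow-ups in 4-36 months rated BI-RADS 1-2 (at least one), or a
  24-36-month follow-up rated BI-RADS 1-3;
* a discordant benign biopsy must be resolved by a non-discordant biopsy or
  surgery within 6 months;
* malignant breasts are kept only when the cancer was plausibly visible on
  ultrasound: BI-RADS 1-2 or no US-guided sampling excludes, BI-RADS 0/3/6
  or multi-modal guidance goes to manual review, BI-RADS 4A-5 with purely
  US-guided sampling is included.

All windows use inclusive endpoints and calendar-day arithmetic; "months"
are fixed 30.44-day multiples rounded to whole days, so boundary tests are
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

MALIGNANT_FINDINGS = frozenset(
    {
        "invasive ductal carcinoma",
        "invasive lobular carcinoma",
        "special-type invasive carcinoma",
        "inflammatory carcinoma",
        "intraductal papillary carcinoma",
        "microinvasive carcinoma",
        "ductal carcinoma in situ",
        "lymphoma",
        "phyllodes",
    }
)

BENIGN_FINDINGS = frozenset(
    {
        "cyst",
        "fibroadenoma",
        "scar",
        "sclerosing adenosis",
        "lobular carcinoma in situ",
        "columnar cell changes",
        "atypical lobular hyperplasia",
        "atypical ductal hyperplasia",
        "papilloma",
        "periductal mastitis",
        "usual ductal hyperplasia",
    }
)

BIRADS_VALUES = ("0", "1", "2", "3", "4A", "4B", "4C", "5", "6", "unknown")
GUIDANCE_VALUES = ("US", "stereotactic", "MRI", "surgery")

LABEL_WINDOW_BEFORE_DAYS = 30
LABEL_WINDOW_AFTER_DAYS = 120

_DAYS_PER_MONTH = 30.44


def months(m: float) -> timedelta:
    """Calendar window arm of m months as a fixed whole-day duration."""
    return timedelta(days=round(_DAYS_PER_MONTH * m))


@dataclass(frozen=True)
class PathologyEvent:
    date: date
    finding: str
    guidance: str = "US"
    concordant: bool = True

    def is_malignant(self) -> bool:
        return _category(self.finding) == "malignant"

    def is_benign(self) -> bool:
        return _category(self.finding) == "benign"


@dataclass(frozen=True)
class FollowUp:
    date: date
    birads: str


@dataclass
class ExamRecord:
    exam_id: str
    patient_id: str
    laterality: str
    exam_date: date
    birads: str
    biopsied: bool
    pathology_events: list[PathologyEvent] = field(default_factory=list)
    followups: list[FollowUp] = field(default_factory=list)
    expected_verdict: str | None = None  # set by generators for test oracles


Decision = Literal["include", "exclude", "manual_review"]


@dataclass(frozen=True)
class EligibilityVerdict:
    decision: Decision
    rule_id: str
    note: str = ""


def _category(finding: str) -> str:
    if finding in MALIGNANT_FINDINGS:
        return "malignant"
    if finding in BENIGN_FINDINGS:
        return "benign"
    raise ValueError(f"unknown finding category: {finding!r}")


def assign_labels(record: ExamRecord) -> tuple[int, int]:
    """(y_benign, y_malignant) from pathology events near the exam date.

    The window is [exam_date - 30 days, exam_date + 120 days], inclusive on
    both ends. Unknown finding terms raise rather than silently dropping.
    """
    lo = record.exam_date - timedelta(days=LABEL_WINDOW_BEFORE_DAYS)
    hi = record.exam_date + timedelta(days=LABEL_WINDOW_AFTER_DAYS)
    y_b = y_m = 0
    for ev in record.pathology_events:
        cat = _category(ev.finding)  # raises on unknown terms
        if lo <= ev.date <= hi:
            if cat == "malignant":
                y_m = 1
            else:
                y_b = 1
    return y_b, y_m


def _malignancy_within(record: ExamRecord, lo: timedelta, hi: timedelta) -> bool:
    for ev in record.pathology_events:
        if ev.is_malignant():
            delta = ev.date - record.exam_date
            if lo <= delta <= hi:
                return True
    return False


def eligible_negative(record: ExamRecord) -> EligibilityVerdict:
    """Eligibility of a non-biopsied BI-RADS 1-2 breast."""
    if record.biopsied or record.birads not in ("1", "2"):
        raise ValueError(
            "eligible_negative requires a non-biopsied BI-RADS 1-2 record, "
            f"got biopsied={record.biopsied}, birads={record.birads}"
        )
    if _malignancy_within(record, timedelta(0), months(15)):
        return EligibilityVerdict("exclude", "neg_malignancy_0_15mo")
    for fu in record.followups:
        delta = fu.date - record.exam_date
        if months(6) <= delta <= months(24) and fu.birads in ("1", "2"):
            return EligibilityVerdict("include", "neg_followup_6_24mo")
    return EligibilityVerdict("exclude", "neg_no_qualifying_followup")


def eligible_probably_benign(record: ExamRecord) -> EligibilityVerdict:
    """Eligibility of a non-biopsied BI-RADS 3 (probably benign) breast."""
    if record.biopsied or record.birads != "3":
        raise ValueError(
            "eligible_probably_benign requires a non-biopsied BI-RADS 3 record, "
            f"got biopsied={record.biopsied}, birads={record.birads}"
        )
    if _malignancy_within(record, timedelta(0), months(15)):
        return EligibilityVerdict("exclude", "pb_malignancy_0_15mo")
    in_4_36 = [
        fu
        for fu in record.followups
        if months(4) <= fu.date - record.exam_date <= months(36)
    ]
    # branch 1: all follow-ups inside 4-36 months downgraded to BI-RADS 1-2,
    # with at least one such follow-up (the vacuous reading is rejected)
    if in_4_36 and all(fu.birads in ("1", "2") for fu in in_4_36):
        return EligibilityVerdict("include", "pb_all_followups_benign")
    # branch 2: a late (24-36 months) follow-up still rated BI-RADS 1-3
    for fu in record.followups:
        delta = fu.date - record.exam_date
        if months(24) <= delta <= months(36) and fu.birads in ("1", "2", "3"):
            return EligibilityVerdict("include", "pb_late_stable_followup")
    return EligibilityVerdict("exclude", "pb_no_qualifying_followup")


def resolve_discordant(record: ExamRecord) -> EligibilityVerdict:
    """Eligibility of a breast whose benign biopsy was discordant.

    The initial discordant biopsy must be resolved by a subsequent
    non-discordant biopsy or surgery within 6 months of it.
    """
    discordant = [
        ev for ev in record.pathology_events if ev.is_benign() and not ev.concordant
    ]
    if not discordant:
        raise ValueError("resolve_discordant requires >=1 discordant benign event")
    first = min(discordant, key=lambda ev: ev.date)
    for ev in record.pathology_events:
        if ev is first or not ev.concordant:
            continue
        delta = ev.date - first.date
        if timedelta(0) <= delta <= months(6):
            return EligibilityVerdict("include", "discordant_resolved")
    return EligibilityVerdict("exclude", "discordant_unresolved")


def cancer_visibility_filter(record: ExamRecord) -> EligibilityVerdict:
    """Eligibility of a malignant-labeled breast: was the cancer on US?

    Guidance logic considers biopsy modalities (US, stereotactic, MRI);
    surgery events carry no imaging guidance and do not trigger review.
    """
    _, y_m = assign_labels(record)
    if not y_m:
        raise ValueError("cancer_visibility_filter requires a malignant-labeled record")
    if record.birads in ("1", "2"):
        return EligibilityVerdict("exclude", "mal_birads_1_2")
    guidances = {
        ev.guidance for ev in record.pathology_events if ev.guidance != "surgery"
    }
    if "US" not in guidances:
        return EligibilityVerdict("exclude", "mal_no_us_guidance")
    if record.birads in ("0", "3", "6"):
        return EligibilityVerdict("manual_review", "mal_birads_0_3_6")
    if guidances & {"stereotactic", "MRI"}:
        return EligibilityVerdict("manual_review", "mal_multimodal_guidance")
    if record.birads in ("4A", "4B", "4C", "5"):
        return EligibilityVerdict("include", "mal_visible_us")
    return EligibilityVerdict("exclude", "unroutable", note=f"birads={record.birads}")


def route_record(record: ExamRecord) -> EligibilityVerdict:
    """Total router: every syntactically valid record gets exactly one verdict."""
    y_b, y_m = assign_labels(record)
    if y_m:
        return cancer_visibility_filter(record)
    if any(ev.is_benign() and not ev.concordant for ev in record.pathology_events):
        return resolve_discordant(record)
    if record.biopsied:
        if y_b:
            return EligibilityVerdict("include", "benign_concordant")
        return EligibilityVerdict(
            "exclude", "unroutable", note="biopsied without in-window findings"
        )
    if record.birads in ("1", "2"):
        return eligible_negative(record)
    if record.birads == "3":
        return eligible_probably_benign(record)
    return EligibilityVerdict("exclude", "unroutable", note=f"birads={record.birads}")


def build_test_set(
    records: Sequence[ExamRecord],
) -> tuple[list[ExamRecord], pd.DataFrame]:
    """Route every record; return included records and a full audit log."""
    included: list[ExamRecord] = []
    rows = []
    for rec in records:
        y_b, y_m = assign_labels(rec)
        verdict = route_record(rec)
        if verdict.decision == "include":
            included.append(rec)
        rows.append(
            {
                "exam_id": rec.exam_id,
                "breast_id": f"{rec.exam_id}-{rec.laterality}",
                "label_benign": y_b,
                "label_malignant": y_m,
                "decision": verdict.decision,
                "rule_id": verdict.rule_id,
                "note": verdict.note,
            }
        )
    audit = pd.DataFrame(
        rows,
        columns=[
            "exam_id",
            "breast_id",
            "label_benign",
            "label_malignant",
            "decision",
            "rule_id",
            "note",
        ],
    )
    return included, audit


# ---------------------------------------------------------------------------
# CSV serialization (one row per record; nested events as JSON columns)


def records_to_frame(records: Iterable[ExamRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {
                "exam_id": rec.exam_id,
                "patient_id": rec.patient_id,
                "laterality": rec.laterality,
                "exam_date": rec.exam_date.isoformat(),
                "birads": rec.birads,
                "biopsied": int(rec.biopsied),
                "pathology_events": json.dumps(
                    [
                        {
                            "date": ev.date.isoformat(),
                            "finding": ev.finding,
                            "guidance": ev.guidance,
                            "concordant": ev.concordant,
                        }
                        for ev in rec.pathology_events
                    ]
                ),
                "followups": json.dumps(
                    [
                        {"date": fu.date.isoformat(), "birads": fu.birads}
                        for fu in rec.followups
                    ]
                ),
                "expected_verdict": rec.expected_verdict or "",
            }
        )
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[ExamRecord]:
    records = []
    for _, row in frame.iterrows():
        records.append(
            ExamRecord(
                exam_id=str(row["exam_id"]),
                patient_id=str(row["patient_id"]),
                laterality=str(row["laterality"]),
                exam_date=date.fromisoformat(str(row["exam_date"])),
                birads=str(row["birads"]),
                biopsied=bool(int(row["biopsied"])),
                pathology_events=[
                    PathologyEvent(
                        date=date.fromisoformat(ev["date"]),
                        finding=ev["finding"],
                        guidance=ev["guidance"],
                        concordant=ev["concordant"],
                    )
                    for ev in json.loads(row["pathology_events"])
                ],
                followups=[
                    FollowUp(date=date.fromisoformat(fu["date"]), birads=fu["birads"])
                    for fu in json.loads(row["followups"])
                ],
                expected_verdict=(str(row["expected_verdict"]) or None)
                if "expected_verdict" in row
                else None,
            )
        )
    return records


def write_records_csv(records: Iterable[ExamRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[ExamRecord]:
    return frame_to_records(pd.read_csv(path, keep_default_na=False))
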