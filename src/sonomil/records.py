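"""Stratified synthetic exam-metadata records for exercising the cohort rules.

Each branch builder constructs a record whose eligibility outcome is known at
construction time (including exact boundary days of every calendar window),
so the rules engine can be validated against intent rather than against
itself. The ``expected_verdict`` field on the returned records carries that
intent; it is metadata for tests, never an input to the rules.
"""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np

from .cohort import ExamRecord, FollowUp, PathologyEvent, months

_BASE_DATE = date(2018, 6, 15)


def _rec(
    i: int,
    birads: str,
    biopsied: bool,
    events: list[PathologyEvent],
    followups: list[FollowUp],
    expected: str,
) -> ExamRecord:
    return ExamRecord(
        exam_id=f"rec-{i:04d}",
        patient_id=f"pat-{i:04d}",
        laterality="L" if i % 2 == 0 else "R",
        exam_date=_BASE_DATE,
        birads=birads,
        biopsied=biopsied,
        pathology_events=events,
        followups=followups,
        expected_verdict=expected,
    )


def _ev(days: int, finding: str, guidance: str = "US", concordant: bool = True) -> PathologyEvent:
    return PathologyEvent(
        date=_BASE_DATE + timedelta(days=days),
        finding=finding,
        guidance=guidance,
        concordant=concordant,
    )


def _fu(days: int, birads: str) -> FollowUp:
    return FollowUp(date=_BASE_DATE + timedelta(days=days), birads=birads)


def _jitter(rng: np.random.Generator, lo: int, hi: int) -> int:
    """A day offset drawn strictly inside [lo, hi] (safe, non-boundary)."""
    return int(rng.integers(lo, hi + 1))


def _branch_builders():
    """One builder per behavioral branch of the rules engine.

    Boundary branches use the exact inclusive endpoint in whole days
    (months are 30.44-day multiples rounded to days: 4mo=122, 6mo=183,
    15mo=457, 24mo=731, 36mo=1096).
    """
    d6, d15, d24, d36, d4 = (months(m).days for m in (6, 15, 24, 36, 4))

    def neg_followup_ok(i, rng):
        return _rec(i, "1", False, [], [_fu(_jitter(rng, d6 + 1, d24 - 1), "2")], "include")

    def neg_followup_6mo_boundary(i, rng):
        return _rec(i, "2", False, [], [_fu(d6, "1")], "include")

    def neg_followup_24mo_boundary(i, rng):
        return _rec(i, "1", False, [], [_fu(d24, "2")], "include")

    def neg_followup_late(i, rng):
        return _rec(i, "2", False, [], [_fu(_jitter(rng, d24 + 30, d36), "2")], "exclude")

    def neg_no_followup(i, rng):
        return _rec(i, "1", False, [], [], "exclude")

    def neg_malignancy_10mo(i, rng):
        days = _jitter(rng, 200, 440)
        return _rec(
            i, "1", False,
            [_ev(days, "invasive ductal carcinoma")],
            [_fu(_jitter(rng, d6 + 1, d24 - 1), "2")],
            "exclude",
        )

    def neg_malignancy_15mo_boundary(i, rng):
        return _rec(
            i, "2", False,
            [_ev(d15, "ductal carcinoma in situ")],
            [_fu(d6 + 10, "1")],
            "exclude",
        )

    def pb_all_followups_benign(i, rng):
        return _rec(
            i, "3", False, [],
            [_fu(_jitter(rng, d4 + 1, 400), "2"), _fu(_jitter(rng, 500, d36 - 1), "1")],
            "include",
        )

    def pb_late_stable_followup(i, rng):
        return _rec(i, "3", False, [], [_fu(_jitter(rng, d24 + 1, d36 - 1), "3")], "include")

    def pb_early_birads3_only(i, rng):
        return _rec(i, "3", False, [], [_fu(_jitter(rng, d4 + 1, d24 - 30), "3")], "exclude")

    def pb_4mo_boundary(i, rng):
        return _rec(i, "3", False, [], [_fu(d4, "1")], "include")

    def pb_36mo_boundary(i, rng):
        return _rec(i, "3", False, [], [_fu(d36, "3")], "include")

    def pb_no_followup(i, rng):
        return _rec(i, "3", False, [], [], "exclude")

    def pb_malignancy(i, rng):
        return _rec(
            i, "3", False,
            [_ev(_jitter(rng, 200, 440), "invasive lobular carcinoma")],
            [_fu(_jitter(rng, d4 + 1, 400), "2")],
            "exclude",
        )

    def discordant_resolved_surgery(i, rng):
        d0 = _jitter(rng, 5, 30)
        return _rec(
            i, "4A", True,
            [
                _ev(d0, "fibroadenoma", concordant=False),
                _ev(d0 + _jitter(rng, 10, 80), "scar", guidance="surgery"),
            ],
            [], "include",
        )

    def discordant_unresolved(i, rng):
        return _rec(
            i, "4A", True,
            [_ev(_jitter(rng, 5, 30), "cyst", concordant=False)],
            [], "exclude",
        )

    def discordant_second_discordant(i, rng):
        d0 = _jitter(rng, 5, 30)
        return _rec(
            i, "4B", True,
            [
                _ev(d0, "fibroadenoma", concordant=False),
                _ev(d0 + _jitter(rng, 10, 80), "papilloma", concordant=False),
            ],
            [], "exclude",
        )

    def discordant_6mo_boundary(i, rng):
        d0 = 10
        return _rec(
            i, "4A", True,
            [
                _ev(d0, "fibroadenoma", concordant=False),
                _ev(d0 + d6, "fibroadenoma"),
            ],
            [], "include",
        )

    def benign_concordant(i, rng):
        return _rec(i, "4A", True, [_ev(_jitter(rng, 1, 100), "cyst")], [], "include")

    def mal_birads2(i, rng):
        return _rec(i, "2", True, [_ev(_jitter(rng, 0, 100), "invasive ductal carcinoma")], [], "exclude")

    def mal_visible(i, rng):
        return _rec(i, "4B", True, [_ev(_jitter(rng, 0, 100), "invasive ductal carcinoma")], [], "include")

    def mal_no_us(i, rng):
        return _rec(
            i, "4C", True,
            [_ev(_jitter(rng, 0, 100), "ductal carcinoma in situ", guidance="stereotactic")],
            [], "exclude",
        )

    def mal_birads0_multimodal(i, rng):
        d0 = _jitter(rng, 0, 60)
        return _rec(
            i, "0", True,
            [
                _ev(d0, "invasive ductal carcinoma"),
                _ev(d0 + 10, "ductal carcinoma in situ", guidance="MRI"),
            ],
            [], "manual_review",
        )

    def mal_birads3_review(i, rng):
        return _rec(i, "3", True, [_ev(_jitter(rng, 0, 100), "phyllodes")], [], "manual_review")

    def mal_birads6_review(i, rng):
        return _rec(i, "6", True, [_ev(_jitter(rng, 0, 100), "invasive ductal carcinoma")], [], "manual_review")

    def mal_multimodal_birads5(i, rng):
        d0 = _jitter(rng, 0, 60)
        return _rec(
            i, "5", True,
            [
                _ev(d0, "invasive lobular carcinoma"),
                _ev(d0 + 5, "invasive lobular carcinoma", guidance="stereotactic"),
            ],
            [], "manual_review",
        )

    def mal_minus30_boundary(i, rng):
        return _rec(i, "4A", True, [_ev(-30, "invasive ductal carcinoma")], [], "include")

    def mal_plus120_boundary(i, rng):
        return _rec(i, "4B", True, [_ev(120, "ductal carcinoma in situ")], [], "include")

    def mal_outside_window(i, rng):
        # malignancy 45 days before the exam: outside the label window, and the
        # biopsy yielded no in-window finding -> unroutable exclusion
        return _rec(i, "4A", True, [_ev(-45, "invasive ductal carcinoma")], [], "exclude")

    def unknown_birads(i, rng):
        return _rec(i, "unknown", False, [], [_fu(300, "2")], "exclude")

    return [
        neg_followup_ok,
        neg_followup_6mo_boundary,
        neg_followup_24mo_boundary,
        neg_followup_late,
        neg_no_followup,
        neg_malignancy_10mo,
        neg_malignancy_15mo_boundary,
        pb_all_followups_benign,
        pb_late_stable_followup,
        pb_early_birads3_only,
        pb_4mo_boundary,
        pb_36mo_boundary,
        pb_no_followup,
        pb_malignancy,
        discordant_resolved_surgery,
        discordant_unresolved,
        discordant_second_discordant,
        discordant_6mo_boundary,
        benign_concordant,
        mal_birads2,
        mal_visible,
        mal_no_us,
        mal_birads0_multimodal,
        mal_birads3_review,
        mal_birads6_review,
        mal_multimodal_birads5,
        mal_minus30_boundary,
        mal_plus120_boundary,
        mal_outside_window,
        unknown_birads,
    ]


def gen_exam_records(n: int, rng: np.random.Generator) -> list[ExamRecord]:
    """Generate n records cycling through every rule branch.

    At n >= 150 every branch appears at least five times. Records carry
    ``expected_verdict`` in {include, exclude, manual_review} as the
    construction-time oracle.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    builders = _branch_builders()
    return [builders[i % len(builders)](i, rng) for i in range(n)]
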