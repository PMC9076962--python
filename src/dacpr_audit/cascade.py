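"""Cohort-construction cascade for the OHCA call audit.

Three sequential filters mirror how audited cohorts are assembled:

1. study-level exclusions — patient alive during the call, voice log missing;
2. the AHA "recognizable OHCA" filter — bystander CPR already in progress or
   a caller-side recognizability barrier (third-party call, hysterical
   caller, hang-up, language barrier, other);
3. the AHA "available for DA-CPR" filter — applied to dispatcher-recognized
   calls with a caller-side barrier to instructed compressions.

Each excluded record is attributed to exactly one reason, in a fixed
priority order, so stage counts always conserve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .records import CallRecord, DacprBarrier, RecognizabilityBarrier

__all__ = [
    "CascadeReport",
    "apply_study_exclusions",
    "classify_recognizable",
    "classify_dacpr_available",
    "build_cascade_report",
]

STUDY_REASONS = ("ALIVE_DURING_CALL", "MISSING_AUDIO")
RECOGNIZABILITY_REASONS = (
    "CPR_IN_PROGRESS",
    "THIRD_PARTY",
    "HYSTERICAL",
    "HANG_UP",
    "LANGUAGE",
    "OTHER",
)
DACPR_REASONS = ("CANNOT_MOVE", "REFUSES", "HANG_UP", "NOT_WITH_PATIENT", "OTHER")


@dataclass
class CascadeReport:
    """Stage counts and per-reason exclusion counts of the audit cascade."""

    n_input: int
    n_included: int
    study_exclusions: dict[str, int]
    n_recognizable: int
    recognizability_exclusions: dict[str, int]
    n_recognized: int
    n_dacpr_available: int
    dacpr_exclusions: dict[str, int]

    def check(self) -> None:
        """Assert the conservation invariants of the cascade."""
        assert self.n_included == self.n_input - sum(self.study_exclusions.values())
        assert self.n_recognizable == self.n_included - sum(
            self.recognizability_exclusions.values()
        )
        assert self.n_dacpr_available == self.n_recognized - sum(
            self.dacpr_exclusions.values()
        )
        counts = [
            self.n_input,
            self.n_included,
            self.n_recognizable,
            self.n_recognized,
            self.n_dacpr_available,
            *self.study_exclusions.values(),
            *self.recognizability_exclusions.values(),
            *self.dacpr_exclusions.values(),
        ]
        assert all(c >= 0 for c in counts)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_included": self.n_included,
            "study_exclusions": dict(self.study_exclusions),
            "n_recognizable": self.n_recognizable,
            "recognizability_exclusions": dict(self.recognizability_exclusions),
            "n_recognized": self.n_recognized,
            "n_dacpr_available": self.n_dacpr_available,
            "dacpr_exclusions": dict(self.dacpr_exclusions),
        }


def apply_study_exclusions(
    records: Sequence[CallRecord],
) -> tuple[list[CallRecord], dict[str, int]]:
    """Drop calls excluded at study level; return (included, reason→count).

    A record matching both reasons is counted once, under ALIVE_DURING_CALL
    (the higher-priority reason).
    """
    included: list[CallRecord] = []
    counts = {reason: 0 for reason in STUDY_REASONS}
    for r in records:
        if r.alive_during_call:
            counts["ALIVE_DURING_CALL"] += 1
        elif not r.audio_available:
            counts["MISSING_AUDIO"] += 1
        else:
            included.append(r)
    return included, counts


def classify_recognizable(record: CallRecord) -> tuple[bool, str]:
    """Is this included call recognizable as OHCA? Returns (flag, reason).

    CPR already in progress takes priority over any recorded barrier.
    """
    if record.cpr_in_progress:
        return False, "CPR_IN_PROGRESS"
    if record.recognizability_barrier is not RecognizabilityBarrier.NONE:
        return False, record.recognizability_barrier.name
    return True, "NONE"


def classify_dacpr_available(record: CallRecord) -> tuple[bool, str]:
    """Is this recognized call available for DA-CPR? Returns (flag, reason)."""
    if not record.recognized:
        raise ValueError(
            f"{record.call_id}: DA-CPR availability is defined only for recognized calls"
        )
    if record.dacpr_barrier is not DacprBarrier.NONE:
        return False, record.dacpr_barrier.name
    return True, "NONE"


@dataclass
class CascadeCohorts:
    """The record subsets at each cascade stage (report plus the data)."""

    included: list[CallRecord] = field(default_factory=list)
    recognizable: list[CallRecord] = field(default_factory=list)
    recognized: list[CallRecord] = field(default_factory=list)
    dacpr_available: list[CallRecord] = field(default_factory=list)


def run_cascade(records: Sequence[CallRecord]) -> tuple[CascadeReport, CascadeCohorts]:
    """Apply all three filters; return the report and each stage's records.

    ``recognized`` is recognized-among-recognizable (the goal-2 numerator and
    the DA-CPR availability denominator).
    """
    included, study_counts = apply_study_exclusions(records)
    cohorts = CascadeCohorts(included=included)

    rec_counts = {reason: 0 for reason in RECOGNIZABILITY_REASONS}
    for r in included:
        ok, reason = classify_recognizable(r)
        if ok:
            cohorts.recognizable.append(r)
        else:
            rec_counts[reason] += 1

    dacpr_counts = {reason: 0 for reason in DACPR_REASONS}
    for r in cohorts.recognizable:
        if not r.recognized:
            continue
        cohorts.recognized.append(r)
        ok, reason = classify_dacpr_available(r)
        if ok:
            cohorts.dacpr_available.append(r)
        else:
            dacpr_counts[reason] += 1

    report = CascadeReport(
        n_input=len(records),
        n_included=len(included),
        study_exclusions=study_counts,
        n_recognizable=len(cohorts.recognizable),
        recognizability_exclusions=rec_counts,
        n_recognized=len(cohorts.recognized),
        n_dacpr_available=len(cohorts.dacpr_available),
        dacpr_exclusions=dacpr_counts,
    )
    report.check()
    return report, cohorts


def build_cascade_report(records: Sequence[CallRecord]) -> CascadeReport:
    """Compose the three classifiers into a :class:`CascadeReport`."""
    report, _ = run_cascade(records)
    return report
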