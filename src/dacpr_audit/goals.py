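"""The five AHA performance measures for dispatcher-assisted CPR.

Goals 1-3 are proportions with percentage benchmarks (75%, 95%, 75%);
goals 4-5 are median times with a high-performance and a minimal-acceptable
threshold (recognition/dispatch < 60 s / < 90 s, first directed compression
< 90 s / < 150 s).  Threshold attainment uses strict ``<`` and the attainment
percentage denominator is the full stage cohort, including records whose
time is missing (a missing time cannot have met a threshold).

Percentages are reported both raw and rounded half-away-from-zero to the
nearest integer, the convention of the audit's printed tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import CallRecord

__all__ = [
    "GoalBenchmark",
    "GoalResult",
    "TimeMetric",
    "DEFAULT_BENCHMARKS",
    "median_iqr",
    "round_half_away",
    "goal1_recognition",
    "goal2_recognizable_recognition",
    "goal3_dacpr_delivery",
    "goal4_time_to_recognition",
    "dispatch_time_metric",
    "goal5_time_to_compression",
    "benchmark",
]


@dataclass(frozen=True)
class GoalBenchmark:
    """AHA benchmark for one performance goal."""

    goal_id: int
    kind: str  # "PROPORTION" | "TIME"
    target_pct: Optional[float] = None
    high_perf_s: Optional[float] = None
    minimal_std_s: Optional[float] = None

    def __post_init__(self):
        if self.kind == "PROPORTION":
            if self.target_pct is None or self.target_pct <= 0:
                raise ValueError("proportion goal needs a positive target_pct")
        elif self.kind == "TIME":
            if self.high_perf_s is None or self.minimal_std_s is None:
                raise ValueError("time goal needs both thresholds")
            if not 0 < self.high_perf_s < self.minimal_std_s:
                raise ValueError("need 0 < high_perf_s < minimal_std_s")
        else:
            raise ValueError(f"unknown goal kind {self.kind!r}")


#: the AHA defaults: goals 1-3 proportion targets, goals 4-5 time thresholds
DEFAULT_BENCHMARKS: dict[str, GoalBenchmark] = {
    "goal1": GoalBenchmark(1, "PROPORTION", target_pct=75),
    "goal2": GoalBenchmark(2, "PROPORTION", target_pct=95),
    "goal3": GoalBenchmark(3, "PROPORTION", target_pct=75),
    "goal4": GoalBenchmark(4, "TIME", high_perf_s=60, minimal_std_s=90),
    "goal5": GoalBenchmark(5, "TIME", high_perf_s=90, minimal_std_s=150),
}


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed-table rule)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class GoalResult:
    """A proportion goal: numerator / denominator against a percentage target."""

    goal_id: int
    label: str
    numerator: int
    denominator: int
    target_pct: Optional[float] = None

    @property
    def pct(self) -> Optional[float]:
        if self.denominator == 0:
            return None
        return 100.0 * self.numerator / self.denominator

    @property
    def pct_rounded(self) -> Optional[int]:
        return None if self.pct is None else round_half_away(self.pct)

    @property
    def met(self) -> bool:
        if self.pct is None or self.target_pct is None:
            return False
        return self.pct >= self.target_pct

    @property
    def undefined(self) -> bool:
        """True when the denominator is empty and the percentage is undefined."""
        return self.denominator == 0

    def to_dict(self) -> dict:
        return {
            "goal_id": self.goal_id,
            "label": self.label,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "pct": self.pct,
            "pct_rounded": self.pct_rounded,
            "target_pct": self.target_pct,
            "met": self.met,
            "undefined": self.undefined,
        }


@dataclass
class TimeMetric:
    """Median/IQR of a time variable plus threshold-attainment counts.

    ``attainment`` maps threshold seconds to ``(count, pct)`` where the count
    is over records with time strictly below the threshold and the percentage
    denominator is the full stage cohort (``denominator``), not just the
    records with a time.
    """

    variable: str
    n_with_time: int
    n_missing: int
    denominator: int
    median_s: Optional[float]
    q1_s: Optional[float]
    q3_s: Optional[float]
    attainment: dict[float, tuple[int, Optional[float]]] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.n_with_time == 0

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "n_with_time": self.n_with_time,
            "n_missing": self.n_missing,
            "denominator": self.denominator,
            "median_s": self.median_s,
            "q1_s": self.q1_s,
            "q3_s": self.q3_s,
            "attainment": {
                str(t): {
                    "count": c,
                    "pct": p,
                    "pct_rounded": None if p is None else round_half_away(p),
                }
                for t, (c, p) in self.attainment.items()
            },
        }


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation of order statistics (type-7)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr: empty input")
    if not np.all(np.isfinite(arr)):
        raise ValueError("median_iqr: non-finite values")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # default = linear (type-7)
    return float(med), float(q1), float(q3)


def _proportion(
    goal_id: int, label: str, numerator: int, denominator: int, target_pct: float
) -> GoalResult:
    return GoalResult(goal_id, label, numerator, denominator, target_pct)


def goal1_recognition(records: Sequence[CallRecord]) -> GoalResult:
    """Goal 1: dispatcher-recognized OHCA among all included calls (target 75%)."""
    num = sum(1 for r in records if r.recognized)
    return _proportion(1, "OHCA recognized, all included", num, len(records), 75)


def goal2_recognizable_recognition(records: Sequence[CallRecord]) -> GoalResult:
    """Goal 2: recognition among recognizable OHCA (target 95%)."""
    num = sum(1 for r in records if r.recognized)
    return _proportion(2, "OHCA recognized, recognizable", num, len(records), 95)


def goal3_dacpr_delivery(
    records: Sequence[CallRecord],
) -> tuple[GoalResult, GoalResult]:
    """Goal 3 over the DA-CPR-available cohort (target 75%).

    Returns the directed-compression result plus the companion
    any-compression-during-call result (directed or bystander-initiated).
    """
    directed = sum(1 for r in records if r.dacpr_compressions_given)
    any_comp = sum(1 for r in records if r.any_compression_during_call is True)
    n = len(records)
    return (
        _proportion(3, "DA-CPR directed compressions given", directed, n, 75),
        _proportion(3, "Any chest compression during call", any_comp, n, 75),
    )


def _time_metric(
    records: Sequence[CallRecord],
    variable: str,
    thresholds: Sequence[float],
) -> TimeMetric:
    times = [getattr(r, variable) for r in records]
    present = [t for t in times if t is not None]
    n = len(records)
    if present:
        med, q1, q3 = median_iqr(present)
    else:
        med = q1 = q3 = None
    attainment: dict[float, tuple[int, Optional[float]]] = {}
    for thr in thresholds:
        count = sum(1 for t in present if t < thr)
        pct = 100.0 * count / n if n else None
        attainment[float(thr)] = (count, pct)
    return TimeMetric(
        variable=variable,
        n_with_time=len(present),
        n_missing=n - len(present),
        denominator=n,
        median_s=med,
        q1_s=q1,
        q3_s=q3,
        attainment=attainment,
    )


def goal4_time_to_recognition(records: Sequence[CallRecord]) -> TimeMetric:
    """Goal 4 (recognition component) over the recognizable cohort.

    Median/IQR over calls with a recognition time; attainment at 60 s / 90 s
    with the full recognizable cohort as denominator.
    """
    return _time_metric(records, "t_recognition_s", (60, 90))


def dispatch_time_metric(records: Sequence[CallRecord]) -> TimeMetric:
    """Goal 4 (dispatch component): time to dispatch of first unit, 60 s / 90 s."""
    return _time_metric(records, "t_dispatch_s", (60, 90))


def goal5_time_to_compression(
    records: Sequence[CallRecord],
) -> tuple[TimeMetric, TimeMetric, TimeMetric]:
    """Goal 5 over the DA-CPR-available cohort, thresholds 90 s / 150 s.

    Returns (any first compression, first DA-CPR-directed compression,
    time to start of CPR instructions).
    """
    any_comp = _time_metric(records, "t_first_compression_s", (90, 150))
    directed = _time_metric(records, "t_first_dacpr_compression_s", (90, 150))
    instructions = _time_metric(records, "t_cpr_instruction_s", (90, 150))
    return any_comp, directed, instructions


def benchmark(
    results: dict[str, object],
    benchmarks: Optional[dict[str, GoalBenchmark]] = None,
) -> dict[str, dict]:
    """Compare goal results and time metrics against their AHA benchmarks.

    ``results`` maps benchmark keys (goal1..goal5, or goal4_dispatch /
    goal5_* variants sharing a base goal's thresholds) to a
    :class:`GoalResult` or :class:`TimeMetric`.  Time medians are compared
    strictly: ``met_high`` iff median < high_perf_s, ``met_minimal`` iff
    median < minimal_std_s.
    """
    benchmarks = benchmarks or DEFAULT_BENCHMARKS
    table: dict[str, dict] = {}
    for key, result in results.items():
        base = key.split("_")[0]
        bm = benchmarks[base]
        if isinstance(result, GoalResult):
            entry = result.to_dict()
            entry["target_pct"] = bm.target_pct
            entry["met"] = result.pct is not None and result.pct >= bm.target_pct
        elif isinstance(result, TimeMetric):
            entry = result.to_dict()
            entry["high_perf_s"] = bm.high_perf_s
            entry["minimal_std_s"] = bm.minimal_std_s
            med = result.median_s
            entry["met_high"] = med is not None and med < bm.high_perf_s
            entry["met_minimal"] = med is not None and med < bm.minimal_std_s
        else:  # pragma: no cover - contract guard
            raise TypeError(f"{key}: unsupported result type {type(result).__name__}")
        table[key] = entry
    return table
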