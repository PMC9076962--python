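"""AHA performance measures: proportions, time metrics, benchmarks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dacpr_audit.cascade import run_cascade
from dacpr_audit.goals import (
    DEFAULT_BENCHMARKS,
    GoalBenchmark,
    TimeMetric,
    benchmark,
    dispatch_time_metric,
    goal1_recognition,
    goal2_recognizable_recognition,
    goal3_dacpr_delivery,
    goal4_time_to_recognition,
    goal5_time_to_compression,
    median_iqr,
    round_half_away,
)
from dacpr_audit.records import CallRecord

from conftest import cohorts


# --- median / IQR -----------------------------------------------------------

def test_singleton_median_iqr():
    assert median_iqr([5]) == (5, 5, 5)


def test_four_point_median_iqr_under_type7():
    med, q1, q3 = median_iqr([1, 2, 3, 4])
    assert (med, q1, q3) == (2.5, 1.75, 3.25)


def test_median_iqr_rejects_empty_and_nonfinite():
    with pytest.raises(ValueError):
        median_iqr([])
    with pytest.raises(ValueError):
        median_iqr([1.0, float("nan")])


def _sort_oracle(values):
    """Independent type-7 quantile: linear interpolation on sorted values."""
    xs = sorted(values)
    n = len(xs)

    def q(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    return q(0.5), q(0.25), q(0.75)


@given(st.lists(st.floats(0, 1e4, allow_nan=False), min_size=1, max_size=200))
def test_median_iqr_matches_sort_based_oracle(values):
    got = median_iqr(values)
    expected = _sort_oracle(values)
    assert got == pytest.approx(expected, abs=1e-9)


# --- proportion goals -------------------------------------------------------

def test_goal1_on_reference_cohort(paper_cohort):
    _, stages = run_cascade(paper_cohort)
    g1 = goal1_recognition(stages.included)
    assert (g1.numerator, g1.denominator) == (742, 936)
    assert g1.pct_rounded == 79
    assert g1.met


def test_goal2_on_reference_cohort(paper_cohort):
    _, stages = run_cascade(paper_cohort)
    g2 = goal2_recognizable_recognition(stages.recognizable)
    assert (g2.numerator, g2.denominator) == (645, 760)
    assert g2.pct_rounded == 85
    assert not g2.met


def test_goal3_on_reference_cohort(paper_cohort):
    _, stages = run_cascade(paper_cohort)
    directed, any_comp = goal3_dacpr_delivery(stages.dacpr_available)
    assert (directed.numerator, directed.denominator) == (343, 560)
    assert directed.pct_rounded == 61 and not directed.met
    assert (any_comp.numerator, any_comp.denominator) == (504, 560)
    assert any_comp.pct_rounded == 90


def test_zero_recognition_and_empty_cohort_edge_cases():
    cohort = [CallRecord(call_id=f"Z{i}") for i in range(10)]
    g = goal1_recognition(cohort)
    assert g.pct == 0 and not g.met
    empty = goal1_recognition([])
    assert empty.pct is None and empty.undefined and not empty.met


@given(cohorts())
def test_goal_counts_equal_recount_oracle(cohort):
    g1 = goal1_recognition(cohort)
    assert g1.numerator == sum(r.recognized for r in cohort)
    assert g1.denominator == len(cohort)
    directed, any_comp = goal3_dacpr_delivery(cohort)
    assert directed.numerator == sum(r.dacpr_compressions_given for r in cohort)
    assert any_comp.numerator == sum(
        r.any_compression_during_call is True for r in cohort
    )


# --- time metrics -----------------------------------------------------------

def test_goal4_attainment_on_reference_cohort(paper_cohort):
    _, stages = run_cascade(paper_cohort)
    g4 = goal4_time_to_recognition(stages.recognizable)
    assert g4.denominator == 760
    assert g4.n_with_time == 528
    assert g4.attainment[60.0][0] == 150
    assert round_half_away(g4.attainment[60.0][1]) == 20
    assert g4.attainment[90.0][0] == 267
    assert round_half_away(g4.attainment[90.0][1]) == 35

    dispatch = dispatch_time_metric(stages.recognizable)
    assert dispatch.attainment[60.0][0] == 154
    assert round_half_away(dispatch.attainment[60.0][1]) == 20
    assert dispatch.attainment[90.0][0] == 386
    assert round_half_away(dispatch.attainment[90.0][1]) == 51


def test_goal5_attainment_on_reference_cohort(paper_cohort):
    _, stages = run_cascade(paper_cohort)
    any_comp, directed, instructions = goal5_time_to_compression(stages.dacpr_available)
    assert any_comp.denominator == directed.denominator == 560
    assert any_comp.attainment[90.0][0] == 31
    assert round_half_away(any_comp.attainment[90.0][1]) == 6
    assert any_comp.attainment[150.0][0] == 109
    assert round_half_away(any_comp.attainment[150.0][1]) == 19
    assert directed.attainment[90.0][0] == 9
    assert directed.attainment[150.0][0] == 52
    assert round_half_away(directed.attainment[150.0][1]) == 9
    assert instructions.n_with_time == 336


def test_equal_times_make_degenerate_quartiles_and_strict_attainment():
    cohort = [
        CallRecord(call_id=f"T{i}", recognized=True, t_recognition_s=60.0)
        for i in range(8)
    ]
    metric = goal4_time_to_recognition(cohort)
    assert metric.median_s == metric.q1_s == metric.q3_s == 60.0
    assert metric.attainment[60.0][0] == 0  # strict "<"
    assert metric.attainment[90.0][0] == 8


def test_no_compressions_yields_flagged_empty_metric():
    cohort = [CallRecord(call_id=f"N{i}", recognized=True) for i in range(5)]
    any_comp, directed, _ = goal5_time_to_compression(cohort)
    assert any_comp.empty and directed.empty
    assert any_comp.median_s is None
    assert any_comp.attainment[90.0] == (0, 0.0)


@given(cohorts())
def test_attainment_counts_monotone_in_threshold(cohort):
    metric = goal4_time_to_recognition(cohort)
    counts = [metric.attainment[t][0] for t in sorted(metric.attainment)]
    assert counts == sorted(counts)
    present = [r.t_recognition_s for r in cohort if r.t_recognition_s is not None]
    for threshold in (60.0, 90.0):
        assert metric.attainment[threshold][0] == sum(t < threshold for t in present)


# --- benchmark verdicts -----------------------------------------------------

def _metric_with_median(variable, median):
    return TimeMetric(
        variable=variable,
        n_with_time=1,
        n_missing=0,
        denominator=1,
        median_s=median,
        q1_s=median,
        q3_s=median,
    )


def test_reference_medians_verdicts():
    table = benchmark(
        {
            "goal4": _metric_with_median("t_recognition_s", 113),
            "goal4_dispatch": _metric_with_median("t_dispatch_s", 87),
            "goal5": _metric_with_median("t_first_dacpr_compression_s", 240),
        }
    )
    assert not table["goal4"]["met_high"] and not table["goal4"]["met_minimal"]
    assert not table["goal4_dispatch"]["met_high"]
    assert table["goal4_dispatch"]["met_minimal"]
    assert not table["goal5"]["met_high"] and not table["goal5"]["met_minimal"]


def test_boundary_median_is_strictly_compared():
    table = benchmark({"goal4": _metric_with_median("t_recognition_s", 90.0)})
    assert not table["goal4"]["met_minimal"]


def test_benchmark_validation():
    with pytest.raises(ValueError):
        GoalBenchmark(4, "TIME", high_perf_s=90, minimal_std_s=60)
    with pytest.raises(ValueError):
        GoalBenchmark(1, "PROPORTION")


# --- printed-percentage rounding --------------------------------------------

@pytest.mark.parametrize(
    "numerator, denominator, printed",
    [
        (742, 936, 79),
        (645, 760, 85),
        (343, 560, 61),
        (504, 560, 90),
        (150, 760, 20),
        (267, 760, 35),
        (117, 760, 15),
        (154, 760, 20),
        (386, 760, 51),
        (31, 560, 6),
        (109, 560, 19),
        (136, 560, 24),
        (9, 560, 2),
        (52, 560, 9),
        (66, 936, 7),
        (318, 936, 34),
        (550, 936, 59),
        (348, 936, 37),
        (259, 936, 28),
        (677, 936, 72),
        (531, 936, 57),
        (97, 936, 10),
        (512, 936, 55),
        (170, 936, 18),
        (488, 936, 52),
    ],
)
def test_rounding_reproduces_every_printed_percentage(numerator, denominator, printed):
    assert round_half_away(100 * numerator / denominator) == printed
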