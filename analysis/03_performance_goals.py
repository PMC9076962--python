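#!/usr/bin/env python
"""Audit both cohorts against the five AHA DA-CPR performance goals.

On the reference-count preset the goal percentages are 79% recognition
(goal 1, target 75%, met), 85% among recognizable (goal 2, target 95%, not
met), 61% directed compressions (goal 3, target 75%, not met; 90% any
compression), with threshold attainment 20% recognition < 60 s, 51%
dispatch < 90 s and 19% compression < 150 s.  Full reports (JSON + markdown
+ survival-curve CSVs) land under ``results/audit_<name>/``.
"""

from pathlib import Path

from dacpr_audit.report import run_audit

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    for name in ("paper_counts", "cohort"):
        report = run_audit(SCRATCH / f"{name}.csv", RESULTS / f"audit_{name}")
        goals = report["goals"]
        print(f"--- {name}")
        for key in ("goal1", "goal2", "goal3", "goal3_any_compression"):
            g = goals[key]
            verdict = "met" if g["met"] else "not met"
            print(
                f"  {key}: {g['numerator']}/{g['denominator']} = {g['pct_rounded']}% "
                f"(target {g['target_pct']}%, {verdict})"
            )
        for key in ("goal4", "goal4_dispatch", "goal5"):
            g = goals[key]
            print(
                f"  {key} ({g['variable']}): median {g['median_s']:.0f} s "
                f"[{g['q1_s']:.0f}, {g['q3_s']:.0f}] — high/minimal standard: "
                f"{g['met_high']}/{g['met_minimal']}"
            )


if __name__ == "__main__":
    main()
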