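#!/usr/bin/env python
"""Build the exclusion cascade for both cohorts.

On the reference-count preset the stages are exactly 1000 calls sampled,
936 included (35 alive during the call, 29 without a voice log), 760
recognizable OHCA, 645 recognized among recognizable and 560 available for
DA-CPR.  Writes ``results/cascade_<name>.json``.
"""

import json
from pathlib import Path

from dacpr_audit.cascade import build_cascade_report
from dacpr_audit.records import read_call_table

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    for name in ("paper_counts", "cohort"):
        records = read_call_table(SCRATCH / f"{name}.csv")
        report = build_cascade_report(records)
        out = RESULTS / f"cascade_{name}.json"
        out.write_text(json.dumps(report.to_dict(), indent=2))
        print(
            f"{name}: {report.n_input} sampled -> {report.n_included} included -> "
            f"{report.n_recognizable} recognizable -> {report.n_recognized} recognized -> "
            f"{report.n_dacpr_available} available for DA-CPR  ({out.name})"
        )


if __name__ == "__main__":
    main()
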