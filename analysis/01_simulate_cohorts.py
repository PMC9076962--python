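#!/usr/bin/env python
"""Generate the working cohorts: a seeded synthetic sample and the
deterministic reference-count preset.

Writes ``scratch/cohort.csv`` (stochastic, 1000 calls, seed 1) and
``scratch/paper_counts.csv`` (deterministic categorical structure with
every stage count exact), both in the canonical call-table schema.
"""

import argparse
from pathlib import Path

from dacpr_audit.simulate import GeneratorParams, generate_cohort, paper_counts_cohort
from dacpr_audit.records import write_call_table

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--n", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    cohort = generate_cohort(GeneratorParams(n=args.n, seed=args.seed))
    write_call_table(cohort, SCRATCH / "cohort.csv")
    print(f"wrote {len(cohort)} synthetic calls (seed {args.seed}) -> scratch/cohort.csv")

    preset = paper_counts_cohort()
    write_call_table(preset, SCRATCH / "paper_counts.csv")
    print(f"wrote {len(preset)} reference-count calls -> scratch/paper_counts.csv")


if __name__ == "__main__":
    main()
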