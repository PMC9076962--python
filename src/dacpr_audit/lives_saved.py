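"""Counterfactual additional-survivors estimator.

The estimator stratifies a cohort by whether a delay variable met a time
target, differences the 30-day survival rates of the two strata, and
multiplies by the number of patients missing the target:

    additional lives = floor[ (p_met - p_not_met) * n_not_met ]

Missing delay times count as "not meeting the target" (they cannot have met
it).  Records with unknown 30-day outcome are excluded from the survival
rates but retained in the multiplier, which counts patients.  The integer
estimate is the floor of the raw product, never rounded up, and a negative
raw effect is reported as zero additional lives with a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .records import CallRecord

__all__ = [
    "LivesSavedInput",
    "LivesSavedEstimate",
    "survival_rates_by_target",
    "estimate_additional_lives",
    "extrapolate_national",
]


@dataclass(frozen=True)
class LivesSavedInput:
    """Stratum survival rates and the size of the target-missing stratum."""

    p_met: float
    p_not_met: float
    n_not_met: int

    def __post_init__(self):
        if not (0 <= self.p_met <= 1 and 0 <= self.p_not_met <= 1):
            raise ValueError("survival proportions must lie in [0, 1]")
        if self.n_not_met < 0:
            raise ValueError("n_not_met must be non-negative")


@dataclass(frozen=True)
class LivesSavedEstimate:
    """Raw and floored additional-lives estimate, with its inputs echoed."""

    inputs: LivesSavedInput
    raw: float
    additional_lives: int
    negative_effect: bool

    def to_dict(self) -> dict:
        return {
            "p_met": self.inputs.p_met,
            "p_not_met": self.inputs.p_not_met,
            "n_not_met": self.inputs.n_not_met,
            "raw": self.raw,
            "additional_lives": self.additional_lives,
            "negative_effect": self.negative_effect,
        }


def survival_rates_by_target(
    records: Sequence[CallRecord], time_field: str, threshold_s: float
) -> LivesSavedInput:
    """Stratify a cohort at ``time_field < threshold_s`` and compute the inputs.

    The met stratum is records whose time is present and strictly below the
    threshold; everything else (time at/over threshold, or time missing) is
    the not-met stratum.  Survival proportions use records with a known
    30-day outcome only; ``n_not_met`` counts the whole not-met stratum.
    """
    met_known = met_survived = 0
    not_met_known = not_met_survived = 0
    n_not_met = 0
    for r in records:
        t = getattr(r, time_field)
        in_met = t is not None and t < threshold_s
        if not in_met:
            n_not_met += 1
        if r.survived_30d is None:
            continue
        if in_met:
            met_known += 1
            met_survived += int(r.survived_30d)
        else:
            not_met_known += 1
            not_met_survived += int(r.survived_30d)
    if met_known == 0:
        raise ValueError(
            f"{time_field} < {threshold_s}: no known outcomes in the target-meeting stratum"
        )
    if not_met_known == 0:
        raise ValueError(
            f"{time_field} < {threshold_s}: no known outcomes in the target-missing stratum"
        )
    return LivesSavedInput(
        p_met=met_survived / met_known,
        p_not_met=not_met_survived / not_met_known,
        n_not_met=n_not_met,
    )


def estimate_additional_lives(inputs: LivesSavedInput) -> LivesSavedEstimate:
    """Apply the estimator: floor of the rate difference times the stratum size."""
    raw = (inputs.p_met - inputs.p_not_met) * inputs.n_not_met
    if raw >= 0:
        lives = int(math.floor(raw))
        negative = False
    else:
        lives = 0
        negative = True
    return LivesSavedEstimate(
        inputs=inputs, raw=raw, additional_lives=lives, negative_effect=negative
    )


def extrapolate_national(
    additional_lives: int, sample_n: int, national_n: int
) -> float:
    """Scale a sample estimate to a national case count (an approximation).

    Assumes the national caseload shares the sample's characteristics; the
    result is returned unrounded.
    """
    if sample_n <= 0:
        raise ValueError("sample_n must be positive")
    return additional_lives * national_n / sample_n
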