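"""Seeded synthetic cohorts of audited OHCA emergency calls.

No audited registry of emergency-call voice logs is publicly deposited, so
every pipeline stage is exercised on synthetic cohorts whose statistical
structure emulates the study conditions: the exclusion-cascade frequencies,
the dispatcher-recognition rates, right-skewed (log-normal) event-time
distributions matched to printed median/IQR triples, covariate marginals,
explicit missingness rates, and a 30-day survival probability that decays
logistically with the delay to first chest compression.

Two entry points:

* :func:`generate_cohort` — a stochastic cohort from :class:`GeneratorParams`
  (deterministic for a fixed seed; numpy PCG64 via ``default_rng``);
* :func:`paper_counts_cohort` — a deterministic 1000-call cohort whose
  categorical structure reproduces the reference count cascade exactly
  (times are filled from quantiles so threshold counts are exact; medians on
  this preset are indicative only).

All caller-side delays within one call are driven by a single latent
"call tempo" (comonotone log-normals): a slow call is slow at recognition,
instruction and compression alike.  This preserves each configured marginal
distribution exactly while making the within-call event order
(recognition <= instruction <= directed compression) near-automatic; the
rare upper-tail inversions that remain are clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .records import (
    CallRecord,
    Cause,
    DacprBarrier,
    Location,
    RecognizabilityBarrier,
    Sex,
)

__all__ = [
    "GeneratorParams",
    "calibrate_lognormal",
    "generate_cohort",
    "paper_counts_cohort",
]

_Z75 = float(norm.ppf(0.75))


def calibrate_lognormal(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) matched to a printed median and quartiles.

    ``mu = ln(median)``; sigma averages the upper- and lower-quartile
    implied spreads, ``ln(q3/median)/z75`` and ``ln(median/q1)/z75``, so an
    asymmetric printed IQR is split evenly.
    """
    if not 0 < q1 < median < q3:
        raise ValueError(f"need 0 < q1 < median < q3, got ({median}, {q1}, {q3})")
    mu = float(np.log(median))
    sigma = float((np.log(q3 / median) + np.log(median / q1)) / (2 * _Z75))
    return mu, sigma


# ---------------------------------------------------------------------------
# parameters

_RECOG_CATEGORIES = (
    "NONE",
    "CPR_IN_PROGRESS",
    "THIRD_PARTY",
    "HYSTERICAL",
    "HANG_UP",
    "LANGUAGE",
    "OTHER",
)
_DACPR_CATEGORIES = (
    "NONE",
    "CANNOT_MOVE",
    "REFUSES",
    "HANG_UP",
    "NOT_WITH_PATIENT",
    "OTHER",
)


def _default_time_models() -> dict[str, tuple[float, float, float]]:
    # (median, q1, q3) seconds, per the study's dispatcher-performance table
    return {
        "recognition": (113.0, 62.0, 204.0),
        "dispatch": (88.0, 64.0, 131.0),
        "any_compression": (214.0, 146.0, 315.0),
        "dacpr_compression": (240.0, 176.0, 332.0),
        "instructions": (201.0, 137.0, 300.0),
    }


def _default_recog_probs() -> dict[str, float]:
    # exclusion-barrier frequencies among included calls (denominator 936)
    return {
        "NONE": 760 / 936,
        "CPR_IN_PROGRESS": 97 / 936,
        "THIRD_PARTY": 23 / 936,
        "HYSTERICAL": 10 / 936,
        "HANG_UP": 9 / 936,
        "LANGUAGE": 4 / 936,
        "OTHER": 33 / 936,
    }


def _default_dacpr_probs() -> dict[str, float]:
    # barrier frequencies among recognized recognizable calls (denominator 645)
    return {
        "NONE": 560 / 645,
        "CANNOT_MOVE": 49 / 645,
        "REFUSES": 13 / 645,
        "HANG_UP": 5 / 645,
        "NOT_WITH_PATIENT": 5 / 645,
        "OTHER": 13 / 645,
    }


def _default_covariates() -> dict:
    # marginal probabilities among known values + per-cohort missing rates
    return {
        "patient_female": {"p": 318 / 929, "missing": 7 / 936},
        "caller_female": {"p": 550 / 906, "missing": 30 / 936},
        "caller_alone": {"p": 348 / 891, "missing": 45 / 936},
        "caller_hcp": {"p": 259 / 902, "missing": 34 / 936},
        "caller_knows_victim": {"p": 780 / 901, "missing": 35 / 936},
        "witnessed": {"p": 531 / 907, "missing": 29 / 936},
        "shockable_rhythm": {"p": 170 / 924, "missing": 12 / 936},
        "aed_addressed": {"p": 68 / 854, "missing": 82 / 936},
        "call_continued_until_ems": {"p": 488 / 835, "missing": 101 / 936},
        "location": {
            "RESIDENTIAL": 677 / 932,
            "PUBLIC": 176 / 932,
            "OTHER": 79 / 932,
            "missing": 4 / 936,
        },
        "cause": {
            "CARDIAC": 512 / 879,
            "OVERDOSE": 21 / 879,
            "TRAUMA": 19 / 879,
            "RESPIRATORY": 46 / 879,
            "ASPHYXIA": 28 / 879,
            "SUICIDE": 38 / 879,
            "SUBMERSION": 19 / 879,
            "SIDS": 7 / 879,
            "OTHER": 189 / 879,
        },
        "age": {"median": 72.0, "q1": 61.0, "q3": 81.0, "missing": 0.0},
    }


@dataclass
class GeneratorParams:
    """Parameters of the synthetic-cohort generator.

    Defaults reproduce the study conditions: a 1000-call sample with the
    audit's stage frequencies, recognition rates, log-normal delay models,
    covariate marginals, missingness rates and an overall 30-day survival of
    about 7%.
    """

    n: int = 1000
    seed: int = 0
    # study-level exclusions
    p_alive_during_call: float = 35 / 1000
    p_missing_audio: float = 29 / 1000
    # recognizability category probabilities (among included calls)
    recognizability_probs: dict[str, float] = field(default_factory=_default_recog_probs)
    # dispatcher recognition
    p_recognized_recognizable: float = 645 / 760
    p_recognized_not_recognizable: float = 97 / 176
    # DA-CPR availability and delivery
    dacpr_barrier_probs: dict[str, float] = field(default_factory=_default_dacpr_probs)
    p_dacpr_given: float = 343 / 560
    p_spontaneous_compression: float = 161 / 217
    # delay models: name -> (median, q1, q3) seconds
    time_models: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_time_models
    )
    # missingness rates (per applicable subgroup)
    p_missing_recognition_time: float = 117 / 645
    p_missing_dispatch_time: float = 1 / 936
    p_missing_compression_time: float = 136 / 504
    p_missing_dacpr_time: float = 40 / 343
    p_missing_instruction_time: float = 7 / 343
    p_missing_survival: float = 47 / 936
    # survival model: logit(p) = intercept + slope * delay-to-first-compression
    survival_slope_per_s: float = -0.004
    overall_survival_target: float = 66 / 936
    no_compression_delay_s: float = 900.0
    # covariate marginals
    covariates: dict = field(default_factory=_default_covariates)

    def validate(self) -> None:
        probs = [
            self.p_alive_during_call,
            self.p_missing_audio,
            self.p_recognized_recognizable,
            self.p_recognized_not_recognizable,
            self.p_dacpr_given,
            self.p_spontaneous_compression,
            self.p_missing_recognition_time,
            self.p_missing_dispatch_time,
            self.p_missing_compression_time,
            self.p_missing_dacpr_time,
            self.p_missing_instruction_time,
            self.p_missing_survival,
            self.overall_survival_target,
            *self.recognizability_probs.values(),
            *self.dacpr_barrier_probs.values(),
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for name in ("recognizability_probs", "dacpr_barrier_probs"):
            total = sum(getattr(self, name).values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
        for name, (med, q1, q3) in self.time_models.items():
            if not 0 < q1 < med < q3:
                raise ValueError(f"time model {name!r}: need 0 < q1 < median < q3")

    def with_seed(self, seed: int) -> "GeneratorParams":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# stochastic generator


def _comonotone_times(
    z: np.ndarray, models: dict[str, tuple[float, float]]
) -> dict[str, np.ndarray]:
    """Evaluate each log-normal delay at the shared per-call latent ``z``."""
    return {name: np.exp(mu + sigma * z) for name, (mu, sigma) in models.items()}


def generate_cohort(params: GeneratorParams) -> list[CallRecord]:
    """Draw a synthetic cohort; identical seeds yield identical cohorts."""
    params.validate()
    n = params.n
    rng = np.random.default_rng(params.seed)
    if n == 0:
        return []

    # --- study-level exclusion flags
    u = rng.random(n)
    alive = u < params.p_alive_during_call
    audio_missing = (~alive) & (u < params.p_alive_during_call + params.p_missing_audio)

    # --- recognizability category
    cat_probs = np.array([params.recognizability_probs[c] for c in _RECOG_CATEGORIES])
    recog_cat = rng.choice(len(_RECOG_CATEGORIES), size=n, p=cat_probs)
    cpr_in_progress = recog_cat == _RECOG_CATEGORIES.index("CPR_IN_PROGRESS")
    recognizable = recog_cat == _RECOG_CATEGORIES.index("NONE")

    # --- dispatcher recognition
    p_rec = np.where(
        recognizable,
        params.p_recognized_recognizable,
        params.p_recognized_not_recognizable,
    )
    recognized = rng.random(n) < p_rec

    # --- DA-CPR barrier (defined for recognized recognizable calls)
    dacpr_probs = np.array([params.dacpr_barrier_probs[c] for c in _DACPR_CATEGORIES])
    dacpr_cat = rng.choice(len(_DACPR_CATEGORIES), size=n, p=dacpr_probs)
    dacpr_cat = np.where(recognized & recognizable, dacpr_cat, 0)  # NONE elsewhere
    available = recognized & recognizable & (dacpr_cat == 0)

    # --- compression delivery
    dacpr_given = available & (rng.random(n) < params.p_dacpr_given)
    spontaneous = available & ~dacpr_given & (
        rng.random(n) < params.p_spontaneous_compression
    )
    any_compression = dacpr_given | spontaneous | cpr_in_progress

    # --- event times: shared per-call tempo latent, comonotone log-normals
    fitted = {
        name: calibrate_lognormal(*mqq) for name, mqq in params.time_models.items()
    }
    z = rng.standard_normal(n)
    t = _comonotone_times(z, fitted)
    t["dispatch"] = np.exp(
        fitted["dispatch"][0] + fitted["dispatch"][1] * rng.standard_normal(n)
    )
    # within-call ordering: clamp the rare upper-tail inversions
    t["instructions"] = np.maximum(t["instructions"], t["recognition"])
    t["dacpr_compression"] = np.maximum(t["dacpr_compression"], t["instructions"])
    t["any_compression"] = np.where(
        dacpr_given,
        np.minimum(t["any_compression"], t["dacpr_compression"]),
        t["any_compression"],
    )

    # --- survival before masking: depends on the latent delay to compression
    delay = np.where(any_compression, t["any_compression"], params.no_compression_delay_s)
    included = ~alive & ~audio_missing
    slope = params.survival_slope_per_s
    target = params.overall_survival_target
    calib = delay[included] if included.any() else delay

    def gap(intercept: float) -> float:
        return float(np.mean(expit(intercept + slope * calib))) - target

    intercept = brentq(gap, -30.0, 30.0)
    survived = rng.random(n) < expit(intercept + slope * delay)

    # --- applicability and missingness masks
    has_recognition = recognized & (rng.random(n) >= params.p_missing_recognition_time)
    has_dispatch = rng.random(n) >= params.p_missing_dispatch_time
    has_compression_t = any_compression & (
        rng.random(n) >= params.p_missing_compression_time
    )
    has_dacpr_t = dacpr_given & (rng.random(n) >= params.p_missing_dacpr_time)
    has_instruction_t = dacpr_given & (
        rng.random(n) >= params.p_missing_instruction_time
    )
    survival_known = rng.random(n) >= params.p_missing_survival

    # --- covariates
    cov = params.covariates
    age_mu = cov["age"]["median"]
    age_sigma = (cov["age"]["q3"] - cov["age"]["q1"]) / (2 * _Z75)
    ages = np.clip(np.round(rng.normal(age_mu, age_sigma, n)), 1, 105)
    age_known = rng.random(n) >= cov["age"]["missing"]

    def boolean_cov(name: str) -> tuple[np.ndarray, np.ndarray]:
        spec = cov[name]
        return rng.random(n) < spec["p"], rng.random(n) >= spec["missing"]

    pat_female, pat_sex_known = boolean_cov("patient_female")
    cal_female, cal_sex_known = boolean_cov("caller_female")
    cal_alone, cal_alone_known = boolean_cov("caller_alone")
    cal_hcp, cal_hcp_known = boolean_cov("caller_hcp")
    knows, knows_known = boolean_cov("caller_knows_victim")
    witnessed, witnessed_known = boolean_cov("witnessed")
    shockable, shockable_known = boolean_cov("shockable_rhythm")
    aed, aed_known = boolean_cov("aed_addressed")
    continued, continued_known = boolean_cov("call_continued_until_ems")

    loc_labels = ("RESIDENTIAL", "PUBLIC", "OTHER")
    loc_p = np.array([cov["location"][k] for k in loc_labels])
    loc_idx = rng.choice(3, size=n, p=loc_p / loc_p.sum())
    loc_known = rng.random(n) >= cov["location"]["missing"]

    cause_labels = tuple(k for k in cov["cause"] if k != "missing")
    cause_p = np.array([cov["cause"][k] for k in cause_labels])
    cause_idx = rng.choice(len(cause_labels), size=n, p=cause_p / cause_p.sum())
    cause_missing_rate = 57 / 936
    cause_known = rng.random(n) >= cause_missing_rate

    width = max(4, len(str(n)))
    records: list[CallRecord] = []
    for i in range(n):
        records.append(
            CallRecord(
                call_id=f"S{i + 1:0{width}d}",
                recognized=bool(recognized[i]),
                alive_during_call=bool(alive[i]),
                audio_available=not bool(audio_missing[i]),
                cpr_in_progress=bool(cpr_in_progress[i]),
                dacpr_compressions_given=bool(dacpr_given[i]),
                recognizability_barrier=RecognizabilityBarrier.NONE
                if recognizable[i] or cpr_in_progress[i]
                else RecognizabilityBarrier[_RECOG_CATEGORIES[recog_cat[i]]],
                dacpr_barrier=DacprBarrier[_DACPR_CATEGORIES[dacpr_cat[i]]],
                t_recognition_s=round(float(t["recognition"][i]), 1)
                if has_recognition[i]
                else None,
                t_dispatch_s=round(float(t["dispatch"][i]), 1) if has_dispatch[i] else None,
                t_cpr_instruction_s=round(float(t["instructions"][i]), 1)
                if has_instruction_t[i]
                else None,
                t_first_compression_s=round(float(t["any_compression"][i]), 1)
                if has_compression_t[i]
                else None,
                t_first_dacpr_compression_s=round(float(t["dacpr_compression"][i]), 1)
                if has_dacpr_t[i]
                else None,
                any_compression_during_call=bool(any_compression[i]),
                survived_30d=bool(survived[i]) if survival_known[i] else None,
                patient_age=float(ages[i]) if age_known[i] else None,
                patient_sex=(Sex.FEMALE if pat_female[i] else Sex.MALE)
                if pat_sex_known[i]
                else None,
                caller_sex=(Sex.FEMALE if cal_female[i] else Sex.MALE)
                if cal_sex_known[i]
                else None,
                caller_alone=bool(cal_alone[i]) if cal_alone_known[i] else None,
                caller_hcp=bool(cal_hcp[i]) if cal_hcp_known[i] else None,
                caller_knows_victim=bool(knows[i]) if knows_known[i] else None,
                location=Location[loc_labels[loc_idx[i]]] if loc_known[i] else None,
                witnessed=bool(witnessed[i]) if witnessed_known[i] else None,
                cause=Cause[cause_labels[cause_idx[i]]] if cause_known[i] else None,
                shockable_rhythm=bool(shockable[i]) if shockable_known[i] else None,
                aed_addressed=bool(aed[i]) if aed_known[i] else None,
                call_continued_until_ems=bool(continued[i])
                if continued_known[i]
                else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# deterministic reference-count preset


def _bucket_quantile_fill(
    mu: float, sigma: float, buckets: Sequence[tuple[float, Optional[float], int]]
) -> np.ndarray:
    """Deterministic values per (lo, hi, count) bucket of a log-normal.

    Values are the bucket-conditional quantiles at offsets (i+0.5)/count, so
    each bucket receives exactly ``count`` values strictly inside [lo, hi).
    """
    out: list[float] = []
    for lo, hi, count in buckets:
        p_lo = 0.0 if lo <= 0 else float(norm.cdf((np.log(lo) - mu) / sigma))
        p_hi = 1.0 if hi is None else float(norm.cdf((np.log(hi) - mu) / sigma))
        ps = p_lo + (np.arange(count) + 0.5) / count * (p_hi - p_lo)
        out.extend(np.exp(mu + sigma * norm.ppf(ps)))
    return np.asarray(out)


def _scatter_labels(rng: np.random.Generator, n: int, counts: dict) -> np.ndarray:
    """An array of ``n`` labels with exact per-label counts, scattered."""
    total = sum(counts.values())
    if total > n:
        raise ValueError("label counts exceed cohort size")
    labels = np.empty(n, dtype=object)
    pool = []
    for label, count in counts.items():
        pool.extend([label] * count)
    pool.extend([None] * (n - total))
    labels[:] = pool
    return labels[rng.permutation(n)]


def paper_counts_cohort() -> list[CallRecord]:
    """A deterministic 1000-call cohort reproducing the reference counts.

    The cascade over this cohort gives 936 included, 760 recognizable, 645
    recognized, 560 available for DA-CPR; recognition is 742/936 overall and
    645/760 among recognizable; 343/560 receive directed compressions and
    504/560 any compression; every threshold-attainment count, missing-time
    count and the 66/936 survivor count are exact.  Event times are filled
    from bucket-conditional quantiles: threshold counts are exact, medians
    are indicative only.
    """
    fitted = {
        name: calibrate_lognormal(*mqq) for name, mqq in _default_time_models().items()
    }
    records: list[CallRecord] = []

    # 64 study-level exclusions: 35 alive during call, 29 without voice log
    mu_d, s_d = fitted["dispatch"]
    excl_dispatch = _bucket_quantile_fill(mu_d, s_d, [(0, None, 64)])
    for i in range(64):
        records.append(
            CallRecord(
                call_id=f"P{i + 1:04d}",
                alive_during_call=i < 35,
                audio_available=i < 35,  # the other 29 lack audio
                t_dispatch_s=None if i == 0 else round(float(excl_dispatch[i]), 1),
            )
        )

    # 936 included calls, assembled in role blocks
    # 0..96    cpr-in-progress (recognized, non-recognizable)     n=97
    # 97..175  barrier calls (not recognized)                     n=79
    # 176..820 recognizable & recognized                          n=645
    #   176..260  DA-CPR barrier                                  n=85
    #   261..603  available, directed compressions given          n=343
    #   604..764  available, spontaneous compressions             n=161
    #   765..820  available, no compressions                      n=56
    # 821..935 recognizable, not recognized                       n=115
    n_inc = 936
    recognized = np.zeros(n_inc, dtype=bool)
    recognized[0:97] = True
    recognized[176:821] = True
    cpr_in_progress = np.zeros(n_inc, dtype=bool)
    cpr_in_progress[0:97] = True

    barrier = np.array(["NONE"] * n_inc, dtype=object)
    for lo, hi, label in (
        (97, 120, "THIRD_PARTY"),
        (120, 130, "HYSTERICAL"),
        (130, 139, "HANG_UP"),
        (139, 143, "LANGUAGE"),
        (143, 176, "OTHER"),
    ):
        barrier[lo:hi] = label

    dacpr_barrier = np.array(["NONE"] * n_inc, dtype=object)
    for lo, hi, label in (
        (176, 225, "CANNOT_MOVE"),
        (225, 238, "REFUSES"),
        (238, 243, "HANG_UP"),
        (243, 248, "NOT_WITH_PATIENT"),
        (248, 261, "OTHER"),
    ):
        dacpr_barrier[lo:hi] = label

    dacpr_given = np.zeros(n_inc, dtype=bool)
    dacpr_given[261:604] = True
    any_comp = np.zeros(n_inc, dtype=bool)
    any_comp[0:97] = True  # CPR already in progress
    any_comp[261:765] = True  # 343 directed + 161 spontaneous

    times = {
        "recognition": np.full(n_inc, np.nan),
        "dispatch": np.full(n_inc, np.nan),
        "any_compression": np.full(n_inc, np.nan),
        "dacpr_compression": np.full(n_inc, np.nan),
        "instructions": np.full(n_inc, np.nan),
    }

    # recognition: 528 of the 645 recognized recognizable calls have a time
    # (117 missing); bucket counts 150 < 60 s, 117 in [60, 90), 261 >= 90 s
    mu, s = fitted["recognition"]
    rec_vals = _bucket_quantile_fill(mu, s, [(0, 60, 150), (60, 90, 117), (90, None, 261)])
    times["recognition"][176 : 176 + 528] = rec_vals

    # dispatch: all 760 recognizable calls; 154 < 60 s, 232 in [60, 90), 374 >= 90
    mu, s = fitted["dispatch"]
    disp_rec = _bucket_quantile_fill(mu, s, [(0, 60, 154), (60, 90, 232), (90, None, 374)])
    recognizable_idx = np.concatenate([np.arange(176, 821), np.arange(821, 936)])
    times["dispatch"][recognizable_idx] = disp_rec
    times["dispatch"][0:176] = _bucket_quantile_fill(mu, s, [(0, None, 176)])

    # first chest compression among the 504 receivers in the available cohort:
    # 368 with a time (31 < 90 s, 78 in [90, 150), 259 >= 150), 136 missing
    mu, s = fitted["any_compression"]
    comp_vals = _bucket_quantile_fill(mu, s, [(0, 90, 31), (90, 150, 78), (150, None, 259)])
    receivers = np.arange(261, 765)
    times["any_compression"][receivers[:368]] = comp_vals
    times["any_compression"][0:97] = _bucket_quantile_fill(mu, s, [(0, 90, 97)])

    # directed compression among the 343: 303 with a time (9/43/251), 40 missing
    mu, s = fitted["dacpr_compression"]
    dacpr_vals = _bucket_quantile_fill(mu, s, [(0, 90, 9), (90, 150, 43), (150, None, 251)])
    times["dacpr_compression"][261 : 261 + 303] = dacpr_vals

    # CPR instructions among the 343: 336 with a time, 7 missing
    mu, s = fitted["instructions"]
    times["instructions"][261 : 261 + 336] = _bucket_quantile_fill(mu, s, [(0, None, 336)])

    # 30-day survival: exactly 66 survivors and 47 unknown among 936.
    # Survivors are spread with weight expit(-delay/250) over the delay to
    # first compression (no-compression calls at 900 s), via a cumulative
    # quota: survival decays smoothly with delay without being separable.
    delay_eff = np.where(np.isnan(times["any_compression"]), 900.0, times["any_compression"])
    weights = 1.0 / (1.0 + np.exp(delay_eff / 250.0))
    quota = np.cumsum(weights * (66.0 / weights.sum()))
    survived = np.floor(quota + 1e-9) > np.floor(np.concatenate([[0.0], quota[:-1]]) + 1e-9)
    assert int(survived.sum()) == 66

    # covariates: exact reference-table counts, scattered deterministically
    rng = np.random.default_rng(2018)
    survival_known = np.ones(n_inc, dtype=bool)
    non_survivors = np.flatnonzero(~survived)
    survival_known[rng.permutation(non_survivors)[:47]] = False
    pat_sex = _scatter_labels(rng, n_inc, {"FEMALE": 318, "MALE": 611})
    cal_sex = _scatter_labels(rng, n_inc, {"FEMALE": 550, "MALE": 356})
    alone = _scatter_labels(rng, n_inc, {"T": 348, "F": 543})
    hcp = _scatter_labels(rng, n_inc, {"T": 259, "F": 643})
    knows = _scatter_labels(rng, n_inc, {"T": 780, "F": 121})
    loc = _scatter_labels(rng, n_inc, {"RESIDENTIAL": 677, "PUBLIC": 176, "OTHER": 79})
    wit = _scatter_labels(rng, n_inc, {"T": 531, "F": 376})
    cause = _scatter_labels(
        rng,
        n_inc,
        {
            "CARDIAC": 512,
            "OVERDOSE": 21,
            "TRAUMA": 19,
            "RESPIRATORY": 46,
            "ASPHYXIA": 28,
            "SUICIDE": 38,
            "SUBMERSION": 19,
            "SIDS": 7,
            "OTHER": 189,
        },
    )
    shock = _scatter_labels(rng, n_inc, {"T": 170, "F": 754})
    aed = _scatter_labels(rng, n_inc, {"T": 68, "F": 786})
    continued = _scatter_labels(rng, n_inc, {"T": 488, "F": 347})
    ages = np.round(
        np.clip(
            72.0
            + (81.0 - 61.0) / (2 * _Z75) * norm.ppf((np.arange(n_inc) + 0.5) / n_inc),
            1,
            105,
        )
    )[rng.permutation(n_inc)]

    def _opt_time(arr: np.ndarray, i: int) -> Optional[float]:
        v = arr[i]
        return None if np.isnan(v) else round(float(v), 1)

    def _tri(v) -> Optional[bool]:
        return None if v is None else v == "T"

    for i in range(n_inc):
        records.append(
            CallRecord(
                call_id=f"P{i + 65:04d}",
                recognized=bool(recognized[i]),
                alive_during_call=False,
                audio_available=True,
                cpr_in_progress=bool(cpr_in_progress[i]),
                dacpr_compressions_given=bool(dacpr_given[i]),
                recognizability_barrier=RecognizabilityBarrier[barrier[i]],
                dacpr_barrier=DacprBarrier[dacpr_barrier[i]],
                t_recognition_s=_opt_time(times["recognition"], i),
                t_dispatch_s=_opt_time(times["dispatch"], i),
                t_cpr_instruction_s=_opt_time(times["instructions"], i),
                t_first_compression_s=_opt_time(times["any_compression"], i),
                t_first_dacpr_compression_s=_opt_time(times["dacpr_compression"], i),
                any_compression_during_call=bool(any_comp[i]),
                survived_30d=bool(survived[i]) if survival_known[i] else None,
                patient_age=float(ages[i]),
                patient_sex=None if pat_sex[i] is None else Sex[pat_sex[i]],
                caller_sex=None if cal_sex[i] is None else Sex[cal_sex[i]],
                caller_alone=_tri(alone[i]),
                caller_hcp=_tri(hcp[i]),
                caller_knows_victim=_tri(knows[i]),
                location=None if loc[i] is None else Location[loc[i]],
                witnessed=_tri(wit[i]),
                cause=None if cause[i] is None else Cause[cause[i]],
                shockable_rhythm=_tri(shock[i]),
                aed_addressed=_tri(aed[i]),
                call_continued_until_ems=_tri(continued[i]),
            )
        )
    return records
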