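"""Audit report assembly: cascade, goal verdicts, lives saved, curves.

:func:`run_audit` ties the pipeline together for one call table and returns
a JSON-serializable report plus a markdown rendering whose every number is
taken from the JSON (no render-only values).  Registry-level context counts
upstream of the audited sample (cases unavailable at extraction, EMS-
witnessed arrests, regional-dispatch regions, the national caseload) are
carried as fixed metadata: they are not derivable from a call table.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .cascade import run_cascade
from .goals import (
    DEFAULT_BENCHMARKS,
    GoalBenchmark,
    benchmark,
    dispatch_time_metric,
    goal1_recognition,
    goal2_recognizable_recognition,
    goal3_dacpr_delivery,
    goal4_time_to_recognition,
    goal5_time_to_compression,
    round_half_away,
)
from .lives_saved import (
    LivesSavedInput,
    estimate_additional_lives,
    extrapolate_national,
    survival_rates_by_target,
)
from .records import CallRecord, read_call_table, validate_cohort
from .splines import default_knots, fit_spline_logistic, predict_curve

__all__ = [
    "REGISTRY_CONTEXT",
    "DEFAULT_LIVES_SAVED_TARGETS",
    "build_report",
    "run_audit",
    "run_lives_saved",
    "render_markdown",
    "load_report_schema",
    "validate_report",
]

#: fixed registry context of the audited sample (printed counts, not computed)
REGISTRY_CONTEXT = {
    "national_ohca": 6135,
    "excluded_not_available": 1045,
    "excluded_ems_witnessed": 547,
    "excluded_regional_emdc": 531,
    "eligible": 4012,
    "sampled": 1000,
}

#: (label, cohort stage, time field, threshold seconds) for lives-saved rows
DEFAULT_LIVES_SAVED_TARGETS = (
    ("recognition_lt_60", "recognizable", "t_recognition_s", 60.0),
    ("dispatch_lt_60", "included", "t_dispatch_s", 60.0),
    ("compression_lt_90", "dacpr_available", "t_first_compression_s", 90.0),
)

_CURVE_FIELDS = ("t_recognition_s", "t_first_compression_s", "t_dispatch_s")


def _config_dict(config: Optional[dict]) -> dict:
    cfg = {"knots": 4, "conf_level": 0.95, "benchmarks": "AHA defaults"}
    cfg.update(config or {})
    return cfg


def _benchmarks_from_config(config: dict) -> dict[str, GoalBenchmark]:
    custom = config.get("benchmarks")
    if not isinstance(custom, dict):
        return DEFAULT_BENCHMARKS
    out = dict(DEFAULT_BENCHMARKS)
    for key, spec in custom.items():
        base = dict(
            goal_id=DEFAULT_BENCHMARKS[key].goal_id, kind=DEFAULT_BENCHMARKS[key].kind
        )
        base.update(spec)
        out[key] = GoalBenchmark(**base)
    return out


def build_report(
    records: Sequence[CallRecord],
    *,
    config: Optional[dict] = None,
    provenance: Optional[dict] = None,
) -> dict:
    """Assemble the full audit report for a validated cohort."""
    if not records:
        raise ValueError("empty cohort: nothing to audit")
    validate_cohort(records)
    config = _config_dict(config)
    benchmarks = _benchmarks_from_config(config)

    cascade_report, cohorts = run_cascade(records)
    g3_directed, g3_any = goal3_dacpr_delivery(cohorts.dacpr_available)
    results = {
        "goal1": goal1_recognition(cohorts.included),
        "goal2": goal2_recognizable_recognition(cohorts.recognizable),
        "goal3": g3_directed,
        "goal3_any_compression": g3_any,
        "goal4": goal4_time_to_recognition(cohorts.recognizable),
        "goal4_dispatch": dispatch_time_metric(cohorts.recognizable),
    }
    g5_any, g5_directed, g5_instructions = goal5_time_to_compression(
        cohorts.dacpr_available
    )
    results["goal5_any_compression"] = g5_any
    results["goal5"] = g5_directed
    results["goal5_instructions"] = g5_instructions
    goal_table = benchmark(results, benchmarks)

    survivors = sum(1 for r in cohorts.included if r.survived_30d is True)
    known = sum(1 for r in cohorts.included if r.survived_30d is not None)
    n_included = len(cohorts.included)
    overall = {
        "survivors": survivors,
        "n_known": known,
        "denominator": n_included,
        "pct": 100.0 * survivors / n_included if n_included else None,
        "pct_rounded": round_half_away(100.0 * survivors / n_included)
        if n_included
        else None,
    }

    stage_cohorts = {
        "included": cohorts.included,
        "recognizable": cohorts.recognizable,
        "dacpr_available": cohorts.dacpr_available,
    }
    lives_rows = []
    for label, stage, field_name, threshold in DEFAULT_LIVES_SAVED_TARGETS:
        row = {
            "target": label,
            "stage": stage,
            "time_field": field_name,
            "threshold_s": threshold,
        }
        try:
            inputs = survival_rates_by_target(stage_cohorts[stage], field_name, threshold)
            estimate = estimate_additional_lives(inputs)
            row.update(estimate.to_dict())
            row["national_extrapolation"] = extrapolate_national(
                estimate.additional_lives, len(records), REGISTRY_CONTEXT["national_ohca"]
            )
        except ValueError as exc:
            row["error"] = str(exc)
        lives_rows.append(row)

    curves = []
    for field_name in _CURVE_FIELDS:
        curves.append(_curve_block(cohorts.included, field_name, config))

    return {
        "provenance": {
            "tool_version": __version__,
            "config": {k: v for k, v in config.items() if k != "benchmarks"}
            | {"benchmarks": "custom" if isinstance(config.get("benchmarks"), dict) else "AHA defaults"},
            **(provenance or {}),
        },
        "registry_context": dict(REGISTRY_CONTEXT),
        "cascade": cascade_report.to_dict(),
        "goals": goal_table,
        "overall_survival": overall,
        "lives_saved": lives_rows,
        "curves": curves,
    }


def _curve_block(records: Sequence[CallRecord], field_name: str, config: dict) -> dict:
    """Fit the survival-vs-delay spline for one field; degeneracy is reported."""
    times = [getattr(r, field_name) for r in records]
    outcomes = [r.survived_30d for r in records]
    pairs = [(t, y) for t, y in zip(times, outcomes) if t is not None and y is not None]
    block: dict = {"variable": field_name, "n_complete": len(pairs)}
    try:
        xs = [t for t, _ in pairs]
        knots = default_knots(xs, k=int(config.get("knots", 4)))
        model = fit_spline_logistic(
            [t for t, _ in pairs], [y for _, y in pairs], knots
        )
        block.update(
            {
                "knots": list(model.basis.knots),
                "coefficients": [float(c) for c in model.coefficients],
                "converged": model.converged,
                "deviance": model.deviance,
                "n_dropped": model.n_dropped,
            }
        )
    except ValueError as exc:
        block["error"] = str(exc)
    return block


def run_audit(
    input_path,
    out_dir,
    *,
    config: Optional[dict] = None,
    plots: bool = False,
) -> dict:
    """Audit one call table; write report.json, report.md and curve CSVs."""
    input_path = Path(input_path)
    records = read_call_table(input_path)
    if not records:
        raise ValueError(f"{input_path}: header-only table, empty cohort")
    digest = hashlib.sha256(input_path.read_bytes()).hexdigest()
    report = build_report(
        records,
        config=config,
        provenance={"input_path": str(input_path), "input_sha256": digest},
    )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conf_level = float(_config_dict(config)["conf_level"])
    for block in report["curves"]:
        if "error" in block:
            continue
        frame = _export_curve(records, block, conf_level)
        csv_path = out_dir / f"curve_{block['variable']}.csv"
        frame.to_csv(csv_path, index=False)
        block["csv"] = csv_path.name
        if plots:
            block["figure"] = _plot_curve(frame, block, out_dir)

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out_dir / "report.md").write_text(render_markdown(report))
    return report


def _export_curve(records, block: dict, conf_level: float):
    import numpy as np

    from .splines import RCSBasis, SplineLogisticModel

    model = SplineLogisticModel(
        basis=RCSBasis(tuple(block["knots"])),
        coefficients=np.asarray(block["coefficients"]),
        cov_params=None,
        converged=block["converged"],
        n_iter=0,
        deviance=block["deviance"],
        n_obs=block["n_complete"],
        n_dropped=block["n_dropped"],
    )
    # refit to regain the covariance for the band (cheap at audit scale)
    times = [getattr(r, block["variable"]) for r in records]
    outcomes = [r.survived_30d for r in records]
    pairs = [(t, y) for t, y in zip(times, outcomes) if t is not None and y is not None]
    full = fit_spline_logistic(
        [t for t, _ in pairs], [y for _, y in pairs], model.basis.knots
    )
    xs = np.asarray([t for t, _ in pairs])
    grid = np.linspace(float(xs.min()), float(xs.max()), 200)
    band = conf_level if full.cov_params is not None else None
    return predict_curve(full, grid, conf_level=band).to_frame()


def _plot_curve(frame, block: dict, out_dir: Path) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(frame["time_s"], frame["p"], color="tab:blue")
    if "lower" in frame:
        ax.fill_between(
            frame["time_s"], frame["lower"], frame["upper"], alpha=0.2, color="tab:blue"
        )
    ax.set_xlabel(f"{block['variable']} (s)")
    ax.set_ylabel("P(30-day survival)")
    ax.set_ylim(bottom=0)
    name = f"curve_{block['variable']}.png"
    fig.tight_layout()
    fig.savefig(out_dir / name, dpi=150)
    plt.close(fig)
    return name


def run_lives_saved(
    records: Sequence[CallRecord],
    targets: Sequence[tuple[str, float]] = (),
) -> list[dict]:
    """Lives-saved rows for (time_field, threshold) targets over a cohort.

    Each field is evaluated on its audit stage: recognition times on the
    recognizable cohort, dispatch on the included cohort, compression times
    on the DA-CPR-available cohort.
    """
    _, cohorts = run_cascade(records)
    stage_by_field = {
        "t_recognition_s": cohorts.recognizable,
        "t_dispatch_s": cohorts.included,
        "t_first_compression_s": cohorts.dacpr_available,
        "t_first_dacpr_compression_s": cohorts.dacpr_available,
        "t_cpr_instruction_s": cohorts.dacpr_available,
    }
    if not targets:
        targets = [(f, t) for _, _, f, t in DEFAULT_LIVES_SAVED_TARGETS]
    rows = []
    for field_name, threshold in targets:
        if field_name not in stage_by_field:
            raise ValueError(f"unknown time field {field_name!r}")
        row = {"time_field": field_name, "threshold_s": threshold}
        try:
            inputs = survival_rates_by_target(
                stage_by_field[field_name], field_name, threshold
            )
            est = estimate_additional_lives(inputs)
            row.update(est.to_dict())
            row["national_extrapolation"] = extrapolate_national(
                est.additional_lives, len(records), REGISTRY_CONTEXT["national_ohca"]
            )
        except ValueError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# rendering and schema


def _pct(value) -> str:
    return "—" if value is None else f"{value}"


def render_markdown(report: dict) -> str:
    """Markdown rendering; every figure shown comes from the JSON report."""
    c = report["cascade"]
    lines = [
        "# OHCA emergency-call audit",
        "",
        f"Tool version {report['provenance']['tool_version']}.",
        "",
        "## Cohort cascade",
        "",
        f"- calls in sample: {c['n_input']}",
        f"- study exclusions: alive during call {c['study_exclusions']['ALIVE_DURING_CALL']}, "
        f"missing audio {c['study_exclusions']['MISSING_AUDIO']}",
        f"- included: {c['n_included']}",
        f"- not recognizable: "
        + ", ".join(f"{k.lower()} {v}" for k, v in c["recognizability_exclusions"].items()),
        f"- recognizable: {c['n_recognizable']}",
        f"- recognized (among recognizable): {c['n_recognized']}",
        f"- DA-CPR barriers: "
        + ", ".join(f"{k.lower()} {v}" for k, v in c["dacpr_exclusions"].items()),
        f"- available for DA-CPR: {c['n_dacpr_available']}",
        "",
        "## Performance goals",
        "",
        "| goal | result | benchmark | met |",
        "|---|---|---|---|",
    ]
    for key, g in report["goals"].items():
        if "numerator" in g:
            met = "yes" if g["met"] else "no"
            lines.append(
                f"| {key} | {g['numerator']}/{g['denominator']} "
                f"({_pct(g['pct_rounded'])}%) | ≥ {g['target_pct']}% | {met} |"
            )
        else:
            att = ", ".join(
                f"< {thr} s: {a['count']} ({_pct(a['pct_rounded'])}%)"
                for thr, a in g["attainment"].items()
            )
            med = "—" if g["median_s"] is None else f"{g['median_s']:.0f}"
            q1 = "—" if g["q1_s"] is None else f"{g['q1_s']:.0f}"
            q3 = "—" if g["q3_s"] is None else f"{g['q3_s']:.0f}"
            verdict = (
                f"high {'yes' if g['met_high'] else 'no'}, "
                f"minimal {'yes' if g['met_minimal'] else 'no'}"
            )
            lines.append(
                f"| {key} ({g['variable']}) | median {med} [{q1}, {q3}] s; {att}; "
                f"missing {g['n_missing']} | < {g['high_perf_s']:.0f} / "
                f"< {g['minimal_std_s']:.0f} s | {verdict} |"
            )
    o = report["overall_survival"]
    lines += [
        "",
        f"Overall 30-day survival: {o['survivors']}/{o['denominator']} "
        f"({_pct(o['pct_rounded'])}%), outcome known for {o['n_known']}.",
        "",
        "## Estimated additional survivors",
        "",
        "| target | p_met | p_not_met | n_not_met | raw | lives | national |",
        "|---|---|---|---|---|---|---|",
    ]
    for row in report["lives_saved"]:
        if "error" in row:
            lines.append(f"| {row['target']} | — | — | — | — | error | — |")
            continue
        lines.append(
            f"| {row['target']} | {row['p_met']:.4f} | {row['p_not_met']:.4f} | "
            f"{row['n_not_met']} | {row['raw']:.2f} | {row['additional_lives']} | "
            f"{row['national_extrapolation']:.1f} |"
        )
    lines += ["", "## Survival curves", ""]
    for block in report["curves"]:
        if "error" in block:
            lines.append(f"- {block['variable']}: not fitted ({block['error']})")
        else:
            lines.append(
                f"- {block['variable']}: spline with knots "
                + ", ".join(f"{k:.0f}" for k in block["knots"])
                + f" s; deviance {block['deviance']:.2f}; n = {block['n_complete']}"
            )
    return "\n".join(lines) + "\n"


def load_report_schema() -> dict:
    """The structural schema shipped with the package."""
    text = resources.files("dacpr_audit").joinpath("report_schema.json").read_text()
    return json.loads(text)


def validate_report(report: dict, schema: Optional[dict] = None) -> list[str]:
    """Structural validation of a report against the shipped schema.

    Supports the subset of JSON-schema the shipped schema uses: ``type``,
    ``required``, ``properties`` and ``items``.  Returns a list of problem
    descriptions (empty = valid).
    """
    schema = schema or load_report_schema()
    problems: list[str] = []
    _check(report, schema, "$", problems)
    return problems


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "integer": int,
    "number": (int, float),
    "null": type(None),
}


def _check(value, schema: dict, path: str, problems: list[str]) -> None:
    typ = schema.get("type")
    if typ is not None:
        allowed = typ if isinstance(typ, list) else [typ]
        ok = any(
            isinstance(value, _TYPES[t]) and not (t in ("integer", "number") and isinstance(value, bool))
            for t in allowed
        )
        if not ok:
            problems.append(f"{path}: expected {allowed}, got {type(value).__name__}")
            return
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                problems.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _check(value[key], sub, f"{path}.{key}", problems)
    if isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            _check(item, schema["items"], f"{path}[{i}]", problems)
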