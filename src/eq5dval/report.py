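"""Orchestration of the full validation run and report rendering.

``run_full_validation`` executes every stage in the pipeline's canonical
order — feasibility, redistribution, ceiling, informativity, known-groups
(with age regressions), convergent validity, construct validity — records
each stage's result (or its failure reason) and returns a
:class:`ValidationReport`.  A stage failure never aborts later stages.

``render_report`` serialises a report as aligned text tables or as
schema-stable JSON.  Display rounding (1 decimal for percentages, 3 for
utilities and Shannon quantities) happens only here; JSON carries full
precision.  Every stage logs its denominator, since denominators are the
recurring ambiguity in this kind of analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .construct import TheoreticalModelSpec, construct_validity
from .crosswalk import ceiling, redistribution
from .datamodel import DIMENSIONS, SurveyDataset, assess_feasibility
from .informativity import informativity_report
from .io import read_survey
from .valuesets import ValueSet, index_column, load_value_set
from .validity import age_regression, convergent_matrix, known_groups

SECTIONS = (
    "feasibility",
    "redistribution",
    "ceiling",
    "informativity",
    "known_groups",
    "convergent",
    "construct_validity",
)


@dataclass
class ValidationReport:
    sections: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def any_errors(self) -> bool:
        return any(s.get("status") == "error" for s in self.sections.values())


def _to_plain(obj):
    """Recursively convert report payloads to JSON-serialisable plain types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_plain(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return {
            "columns": [str(c) for c in obj.columns],
            "index": [str(i) for i in obj.index],
            "data": _to_plain(obj.to_numpy().tolist()),
        }
    if isinstance(obj, pd.Series):
        return _to_plain(obj.to_dict())
    if isinstance(obj, dict):
        return {_key(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _to_plain(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if obj is pd.NA:
        return None
    return obj


def _key(k) -> str:
    if isinstance(k, tuple):
        return "/".join(str(p) for p in k)
    return str(k)


def run_full_validation(
    survey: Union[str, SurveyDataset],
    vs3: Union[str, ValueSet],
    vs5: Union[str, ValueSet],
    spec: Optional[TheoreticalModelSpec] = None,
) -> ValidationReport:
    """Execute every validation stage; failures are recorded, not raised."""
    dataset = read_survey(survey) if isinstance(survey, str) else survey
    vs3 = load_value_set(vs3) if isinstance(vs3, str) else vs3
    vs5 = load_value_set(vs5) if isinstance(vs5, str) else vs5
    spec = spec or TheoreticalModelSpec()

    from . import __version__ as pkg_version

    report = ValidationReport(
        metadata={
            "software_version": pkg_version,
            "n_records": dataset.n,
            "value_set_3l": vs3.label,
            "value_set_5l": vs5.label,
            "model_seed": spec.seed,
            "dataset_metadata": _to_plain(dataset.metadata),
        }
    )

    index5 = index_column(dataset, vs5)
    index3 = index_column(dataset, vs3)
    report.metadata["n_index_5l"] = int(index5.notna().sum())
    report.metadata["n_index_3l"] = int(index3.notna().sum())

    def _stage(name, fn):
        try:
            data = fn()
        except Exception as exc:  # record and continue
            report.sections[name] = {"status": "error", "reason": str(exc)}
        else:
            report.sections[name] = {"status": "ok", "data": _to_plain(data)}

    _stage("feasibility", lambda: assess_feasibility(dataset))
    _stage("redistribution", lambda: redistribution(dataset))
    _stage("ceiling", lambda: ceiling(dataset).table)
    _stage("informativity", lambda: _informativity_payload(dataset))
    _stage("known_groups", lambda: _known_groups_payload(dataset, index5, index3))
    _stage("convergent", lambda: _convergent_payload(dataset, index5))
    _stage(
        "construct_validity",
        lambda: _construct_payload(dataset, vs5, spec),
    )
    for name in SECTIONS:
        report.sections.setdefault(
            name, {"status": "skipped", "reason": "stage not executed"}
        )
    return report


def _informativity_payload(dataset):
    rep = informativity_report(dataset)
    return {
        "per_dimension": {
            dim: {instr: res for instr, res in per.items()}
            for dim, per in rep.per_dimension.items()
        },
        "pct_change_J": rep.pct_change,
        "rounded_change": rep.rounded_change,
    }


def _known_groups_payload(dataset, index5, index3):
    rep = known_groups(dataset, index5, index3)
    payload = {"anova": rep.results, "skipped": rep.skipped, "regressions": {}}
    for sex in ("male", "female"):
        try:
            payload["regressions"][sex] = age_regression(dataset, index5, sex)
        except ValueError as exc:
            payload["regressions"][sex] = {"status": "skipped", "reason": str(exc)}
    return payload


def _convergent_payload(dataset, index5):
    rep = convergent_matrix(dataset, index5)
    return {"rho": rep.rho, "p": rep.p, "n": rep.n,
            "orientation_note": rep.orientation_note}


def _construct_payload(dataset, vs5, spec):
    res = construct_validity(dataset, vs5, spec)
    return {
        "rmse_int": res.rmse_int,
        "rmse_val": res.rmse_val,
        "q95_int": res.q95_int,
        "coverage_pct": res.coverage,
        "n_train": res.n_train,
        "n_test": res.n_test,
        "n_trees": spec.n_trees,
        "train_fraction": spec.train_fraction,
        "tree_defaults": {
            "min_samples_leaf": spec.min_samples_leaf,
            "max_depth": spec.max_depth,
        },
    }


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_report(report: ValidationReport, format: str = "text") -> str:
    if format == "json":
        return json.dumps(
            {"metadata": _to_plain(report.metadata),
             "sections": _to_plain(report.sections)},
            indent=2, sort_keys=True,
        )
    if format != "text":
        raise ValueError(f"unknown format {format!r}")
    return _render_text(report)


def _fmt(x, nd=3):
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "-"
    return f"{x:.{nd}f}"


def _render_text(report: ValidationReport) -> str:
    lines: list[str] = []
    meta = report.metadata
    lines.append(f"EQ-5D validation report (eq5dval {meta.get('software_version')})")
    lines.append(
        f"N = {meta.get('n_records')}; value sets: "
        f"3L={meta.get('value_set_3l')}, 5L={meta.get('value_set_5l')}"
    )
    for name in SECTIONS:
        sec = report.sections.get(name, {})
        lines.append("")
        lines.append(f"== {name} [{sec.get('status', 'missing')}] ==")
        if sec.get("status") != "ok":
            lines.append(f"   reason: {sec.get('reason', 'unknown')}")
            continue
        data = sec["data"]
        if name == "feasibility":
            lines.append(
                f"   missing: 5L {100 * data['missing_5l']:.1f}%  "
                f"3L {100 * data['missing_3l']:.1f}%  "
                f"VAS {100 * data['missing_vas']:.1f}%  (N={data['n_total']})"
            )
        elif name == "redistribution":
            for dim in DIMENSIONS:
                d = data["dimensions"][dim]
                lines.append(
                    f"   {dim:<20} n_pairs={d['n_pairs']:>5} "
                    f"inconsistency={_fmt(d['inconsistency_pct'], 1)}%"
                )
            lines.append(
                f"   mean inconsistency = "
                f"{_fmt(data['mean_inconsistency_pct'], 1)}%"
            )
        elif name == "ceiling":
            cols = data["columns"]
            for rowname, row in zip(data["index"], data["data"]):
                d = dict(zip(cols, row))
                lines.append(
                    f"   {rowname:<20} 3L {_fmt(d['ceiling_3l'], 1)}%  "
                    f"5L {_fmt(d['ceiling_5l'], 1)}%  "
                    f"change {_fmt(d['change'], 1)}  p={_fmt(d['chi2_p'], 4)}"
                )
        elif name == "informativity":
            for dim in DIMENSIONS:
                per = data["per_dimension"][dim]
                lines.append(
                    f"   {dim:<20} H'3L={_fmt(per['3L']['H'])} "
                    f"H'5L={_fmt(per['5L']['H'])} "
                    f"J'3L={_fmt(per['3L']['J'])} J'5L={_fmt(per['5L']['J'])} "
                    f"dJ'={_fmt(data['pct_change_J'][dim], 1)}%"
                )
        elif name == "known_groups":
            for factor, per in data["anova"].items():
                for instr, fa in per.items():
                    lines.append(
                        f"   {factor:<10} {instr}: F={_fmt(fa['F'], 2)} "
                        f"p={_fmt(fa['p'], 4)} "
                        f"direction_ok={fa['direction_ok']}"
                    )
            for sex, reg in data["regressions"].items():
                if "slope" in reg:
                    lines.append(
                        f"   regression {sex}: index = "
                        f"{_fmt(reg['slope'], 4)}*age + {_fmt(reg['intercept'], 4)} "
                        f"(n={reg['n']})"
                    )
        elif name == "convergent":
            cols = data["rho"]["columns"]
            lines.append("   rho rows: " + ", ".join(data["rho"]["index"]))
            for rowname, row in zip(data["rho"]["index"], data["rho"]["data"]):
                cells = "  ".join(_fmt(v, 2) for v in row)
                lines.append(f"   {rowname:<20} {cells}")
        elif name == "construct_validity":
            lines.append(
                f"   RMSE_int={_fmt(data['rmse_int'])} "
                f"RMSE_val={_fmt(data['rmse_val'])} "
                f"q95={_fmt(data['q95_int'])} "
                f"coverage={_fmt(data['coverage_pct'], 1)}% "
                f"(n_train={data['n_train']}, n_test={data['n_test']})"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Minimal structural schema check (no external JSON-schema dependency)
# ---------------------------------------------------------------------------


def validate_report_json(payload: dict, schema: dict) -> list[str]:
    """Check a rendered JSON report against the checked-in structural schema.

    The schema document lists required top-level keys, required sections and
    per-status required fields.  Returns a list of violations (empty = valid).
    """
    problems = []
    for key in schema.get("required_top_level", []):
        if key not in payload:
            problems.append(f"missing top-level key {key!r}")
    sections = payload.get("sections", {})
    for name in schema.get("required_sections", []):
        if name not in sections:
            problems.append(f"missing section {name!r}")
            continue
        sec = sections[name]
        status = sec.get("status")
        if status not in schema.get("allowed_statuses", []):
            problems.append(f"section {name!r}: bad status {status!r}")
        for fieldname in schema.get("status_requires", {}).get(status or "", []):
            if fieldname not in sec:
                problems.append(f"section {name!r}: missing {fieldname!r}")
    return problems
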