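"""Rendering of detailed per-tool reports and the registry-wide summary table.

The detailed report presents the evidence in translational order — phase C
(predictive performance before implementation), phase B (usability and
potential effect during implementation), phase A (post-implementation impact)
— followed by the final grade with its justification, the engine provenance,
and an appendix with every mixed-evidence resolution trace verbatim.

Output is deterministic: identical inputs give byte-identical documents.
"""

from __future__ import annotations

import csv
import io
import json

from . import __version__ as _ENGINE_VERSION
from .engine import GradeResult, PhaseLevel, RawDirection
from .model import EvidenceStudy, ToolProfile

_LEVEL_TITLES = {
    PhaseLevel.C3: "C3 — Internal validation",
    PhaseLevel.C2: "C2 — External validation (single publication)",
    PhaseLevel.C1: "C1 — External validation (multiple publications)",
    PhaseLevel.B2: "B2 — Potential effect",
    PhaseLevel.B1: "B1 — Usability",
    PhaseLevel.A3: "A3 — Post-implementation impact (subjective/descriptive)",
    PhaseLevel.A2: "A2 — Post-implementation impact (observational)",
    PhaseLevel.A1: "A1 — Post-implementation impact (experimental)",
}

_PHASES = (
    ("C", "Phase C — Predictive performance (before implementation)",
     (PhaseLevel.C1, PhaseLevel.C2, PhaseLevel.C3)),
    ("B", "Phase B — Usability and potential effect (during implementation)",
     (PhaseLevel.B1, PhaseLevel.B2)),
    ("A", "Phase A — Post-implementation impact (after implementation)",
     (PhaseLevel.A1, PhaseLevel.A2, PhaseLevel.A3)),
)

_TOOL_FIELDS = (
    ("name", "Name"),
    ("authors", "Authors"),
    ("year_published", "Year published"),
    ("intended_use", "Intended use"),
    ("target_population", "Target population"),
    ("target_outcome", "Target outcome"),
    ("clinical_setting", "Clinical setting"),
    ("input_data_source", "Input data source"),
    ("input_data_type", "Input data type"),
    ("intended_user", "Intended user"),
    ("recommended_action", "Recommended action"),
    ("local_context_notes", "Local context notes"),
)


class ReportFormatError(ValueError):
    """Unknown output format requested."""


def _md_escape(text: str) -> str:
    return str(text).replace("|", "\\|").replace("\n", " ")


def _md_table(header: list[str], rows: list[list[str]]) -> str:
    lines = ["| " + " | ".join(header) + " |",
             "| " + " | ".join("---" for _ in header) + " |"]
    for row in rows:
        lines.append("| " + " | ".join(_md_escape(c) for c in row) + " |")
    return "\n".join(lines)


def _findings_text(study: EvidenceStudy) -> str:
    parts = []
    for f in study.findings:
        piece = f"{f.measure_name} = {f.value:g}{(' ' + f.units) if f.units else ''}"
        if f.comparator_note:
            piece += f" ({f.comparator_note})"
        parts.append(piece)
    if study.comparator_note:
        parts.append(f"note: {study.comparator_note}")
    return "; ".join(parts) if parts else "—"


def _direction_note(result: GradeResult) -> str:
    if result.grade is PhaseLevel.UNGRADED:
        return "no gradeable evidence"
    if result.grade is PhaseLevel.C0:
        return "internal validation insufficient"
    ev = result.per_level_evidence.get(result.grade.value)
    if ev is None:  # pragma: no cover - defensive
        return ""
    if ev.resolution.raw_direction is RawDirection.ALL_POSITIVE:
        return "all positive"
    return "mixed evidence resolved positive"


def _study_rows(studies: list[EvidenceStudy]) -> list[list[str]]:
    rows = []
    for s in sorted(studies, key=lambda x: x.study_id):
        rows.append([
            s.study_id,
            s.citation or "—",
            str(s.year) if s.year is not None else "—",
            s.design.value,
            s.population_description or "—",
            s.setting_description or "—",
            str(s.match.sample_size) if s.match.sample_size is not None else "—",
            "yes" if s.match.fully_matching else "no",
            s.outcome_category.value if s.outcome_category else "—",
            _findings_text(s),
            s.direction.value,
        ])
    return rows


_STUDY_HEADER = [
    "Study", "Citation", "Year", "Design", "Population", "Setting",
    "Sample size", "Matches spec", "Outcome category", "Findings", "Direction",
]


def build_report(
    tool: ToolProfile,
    studies: list[EvidenceStudy],
    grade_result: GradeResult,
    source: str = "",
) -> dict:
    """Structured (JSON-serialisable) form of the detailed report."""
    by_id = {s.study_id: s for s in studies}
    phases = {}
    for phase_key, phase_title, levels in _PHASES:
        level_sections = []
        for level in levels:
            ev = grade_result.per_level_evidence.get(level.value)
            if ev is None:
                continue
            level_studies = [by_id[sid] for sid in ev.study_ids]
            level_sections.append(
                {
                    "level": level.value,
                    "title": _LEVEL_TITLES[level],
                    "studies": [s.model_dump(mode="json") for s in
                                sorted(level_studies, key=lambda x: x.study_id)],
                    "raw_direction": ev.resolution.raw_direction.value,
                    "resolved_direction": ev.resolution.resolved_direction.value,
                    "resolution_trace": [
                        step.model_dump(mode="json")
                        for step in ev.resolution.resolution_trace
                    ],
                }
            )
        phases[phase_key] = {
            "title": phase_title,
            "levels": level_sections,
            "no_evidence": not level_sections,
        }
    return {
        "tool_information": tool.model_dump(mode="json"),
        "phase_C": phases["C"],
        "phase_B": phases["B"],
        "phase_A": phases["A"],
        "final_grade": {
            "code": grade_result.grade.value,
            "direction_note": _direction_note(grade_result),
            "justification": grade_result.justification,
        },
        "provenance": {
            "engine_version": _ENGINE_VERSION,
            "config": grade_result.config.model_dump(mode="json"),
            "source": source,
            "mixed_evidence_protocol": (
                "calibrated reconstruction; see package methods documentation"
            ),
        },
    }


def _render_markdown(report: dict) -> str:
    tool = report["tool_information"]
    out: list[str] = [f"# GRASP Detailed Report — {tool['name']}", ""]

    out.append("## Tool information")
    out.append("")
    rows = []
    for field, label in _TOOL_FIELDS:
        value = tool.get(field)
        if value is None or value == "" or value == []:
            value = "—"
        if isinstance(value, list):
            value = "; ".join(value)
        rows.append([label, str(value)])
    out.append(_md_table(["Field", "Value"], rows))
    out.append("")

    traces = []
    for key in ("phase_C", "phase_B", "phase_A"):
        section = report[key]
        out.append(f"## {section['title']}")
        out.append("")
        if section["no_evidence"]:
            out.append("_No published evidence._")
            out.append("")
            continue
        for level in section["levels"]:
            out.append(f"### {level['title']}")
            out.append("")
            studies = [EvidenceStudy.model_validate(s) for s in level["studies"]]
            out.append(_md_table(_STUDY_HEADER, _study_rows(studies)))
            out.append("")
            direction = level["resolved_direction"]
            if level["raw_direction"] == "mixed":
                out.append(
                    f"Direction of evidence: **mixed**, resolved **{direction}** "
                    "(see appendix for the resolution trace)."
                )
                traces.append(level)
            else:
                out.append(f"Direction of evidence: **{direction}**.")
            out.append("")

    final = report["final_grade"]
    out.append(f"## Final grade: {final['code']}")
    out.append("")
    for line in final["justification"].splitlines():
        out.append(f"- {line}")
    out.append("")

    prov = report["provenance"]
    out.append("## Provenance")
    out.append("")
    out.append(f"- Engine version: {prov['engine_version']}")
    out.append(f"- Resolver config: `{json.dumps(prov['config'], sort_keys=True)}`")
    if prov["source"]:
        out.append(f"- Source: {prov['source']}")
    out.append(f"- Mixed-evidence protocol: {prov['mixed_evidence_protocol']}")
    out.append("")

    out.append("## Appendix — mixed-evidence resolutions")
    out.append("")
    if not traces:
        out.append("_No mixed evidence required resolution._")
        out.append("")
    else:
        for level in traces:
            out.append(f"### {level['title']}")
            out.append("")
            for step in level["resolution_trace"]:
                tally = (
                    " — " + ", ".join(
                        f"{k}: {v:g}" for k, v in step["tally"].items()
                    )
                    if step["tally"]
                    else ""
                )
                ids = ", ".join(step["studies_considered"]) or "(none)"
                note = f" — {step['note']}" if step["note"] else ""
                out.append(f"1. **{step['rule']}**: {ids}{tally}{note}")
            out.append("")
    return "\n".join(out)


def render_detail(
    tool: ToolProfile,
    studies: list[EvidenceStudy],
    grade_result: GradeResult,
    format: str = "markdown",
    source: str = "",
) -> str:
    """Render the detailed report for one tool as markdown or JSON."""
    report = build_report(tool, studies, grade_result, source=source)
    if format in ("markdown", "md"):
        return _render_markdown(report) + "\n"
    if format == "json":
        return json.dumps(report, indent=2) + "\n"
    raise ReportFormatError(f"unknown report format {format!r}; use markdown or json")


_SUMMARY_HEADER = [
    "Tool", "Year", "Intended use", "Highest phase", "Level",
    "Direction of evidence", "Final grade",
]


def summary_rows(
    grade_results: list[GradeResult], tools: dict[str, ToolProfile]
) -> list[list[str]]:
    rows = []
    for result in grade_results:
        tool = tools[result.tool_id]
        grade = result.grade
        rows.append([
            tool.name,
            str(tool.year_published),
            tool.intended_use,
            grade.phase or "—",
            str(grade.level) if grade.level is not None else "—",
            _direction_note(result),
            grade.value,
        ])
    return rows


def render_summary(
    grade_results: list[GradeResult],
    tools: dict[str, ToolProfile],
    format: str = "markdown",
) -> str:
    """Render the registry-wide summary table (one row per tool)."""
    rows = summary_rows(grade_results, tools)
    if format in ("markdown", "md"):
        return _md_table(_SUMMARY_HEADER, rows) + "\n"
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(_SUMMARY_HEADER)
        writer.writerows(rows)
        return buf.getvalue()
    if format == "json":
        records = [dict(zip(_SUMMARY_HEADER, row)) for row in rows]
        return json.dumps(records, indent=2) + "\n"
    raise ReportFormatError(
        f"unknown summary format {format!r}; use markdown, json or csv"
    )
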