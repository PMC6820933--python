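"""Reading, writing and validating evidence registries.

JSON is the canonical on-disk form; YAML 1.2 is accepted on input and output;
CSV is a flat convenience form with one record per row (``record_type`` column
distinguishes the registry header, tools and studies; list- and object-valued
cells hold JSON strings).

:func:`load_registry` enforces structure — parseability, field types, enum
values, id uniqueness and referential integrity. Semantic invariants that a
structurally sound registry may still violate (e.g. an impact study missing
its outcome category) are reported by :func:`validate_registry` as findings,
so a curator can fix a registry incrementally.
"""

from __future__ import annotations

import csv
import io
import json
from pathlib import Path
from typing import Union

import pydantic
import yaml

from .model import (
    PROPORTION_MEASURES,
    EvaluationAspect,
    EvidenceStudy,
    ProportionScale,
    ReferentialIntegrityError,
    Registry,
    RegistryFormatError,
    RegistryValidationError,
    ToolProfile,
    ValidationFinding,
)

_FORMATS = ("json", "yaml", "csv")

# fixed CSV column order so exports are diff-stable
_CSV_COLUMNS = [
    "record_type", "schema_version", "proportion_scale",
    "tool_id", "study_id", "payload",
]


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".json",):
        return "json"
    if suffix in (".yaml", ".yml"):
        return "yaml"
    if suffix in (".csv",):
        return "csv"
    raise RegistryFormatError(
        f"cannot auto-detect registry format from suffix {suffix!r} "
        f"(expected .json, .yaml/.yml or .csv)"
    )


def _registry_from_mapping(data: object, source: str) -> Registry:
    if not isinstance(data, dict):
        raise RegistryFormatError(f"{source}: top level must be a mapping")
    try:
        return Registry.model_validate(data)
    except pydantic.ValidationError as exc:
        msg = str(exc)
        if "dangling tool_id" in msg:
            raise ReferentialIntegrityError(f"{source}: {msg}") from exc
        raise RegistryValidationError(f"{source}: {msg}") from exc


def _parse_csv(text: str, source: str) -> Registry:
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise RegistryFormatError(f"{source}: empty CSV (no header row)")
    missing = {"record_type", "payload"} - set(reader.fieldnames)
    if missing:
        raise RegistryFormatError(
            f"{source}: CSV header missing column(s) {sorted(missing)}"
        )
    meta: dict = {"schema_version": "1.0", "proportion_scale": "percent"}
    tools: list[dict] = []
    studies: list[dict] = []
    for lineno, row in enumerate(reader, start=2):
        kind = (row.get("record_type") or "").strip().lower()
        if kind == "registry":
            if row.get("schema_version"):
                meta["schema_version"] = row["schema_version"]
            if row.get("proportion_scale"):
                meta["proportion_scale"] = row["proportion_scale"]
            continue
        try:
            payload = json.loads(row["payload"])
        except (json.JSONDecodeError, TypeError) as exc:
            raise RegistryFormatError(
                f"{source}: line {lineno}: payload cell is not valid JSON ({exc})"
            ) from exc
        if kind == "tool":
            tools.append(payload)
        elif kind == "study":
            studies.append(payload)
        else:
            raise RegistryFormatError(
                f"{source}: line {lineno}: unknown record_type {kind!r}"
            )
    return _registry_from_mapping(
        {**meta, "tools": tools, "studies": studies}, source
    )


def load_registry(path: Union[str, Path], format: str = "auto") -> Registry:
    """Load and structurally validate a registry file.

    Parameters
    ----------
    path:
        Registry file path.
    format:
        ``json``, ``yaml``, ``csv`` or ``auto`` (detect from suffix).
    """
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    if format not in _FORMATS:
        raise RegistryFormatError(f"unknown registry format {format!r}")
    text = path.read_text(encoding="utf-8")
    source = str(path)
    if format == "csv":
        return _parse_csv(text, source)
    if format == "json":
        try:
            data = json.loads(text) if text.strip() else {}
        except json.JSONDecodeError as exc:
            raise RegistryFormatError(
                f"{source}: line {exc.lineno}: {exc.msg}"
            ) from exc
    else:
        try:
            data = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise RegistryFormatError(f"{source}: {exc}") from exc
    return _registry_from_mapping(data, source)


def registry_to_mapping(registry: Registry) -> dict:
    """Plain-python mapping form of a registry (JSON/YAML serialisable)."""
    return registry.model_dump(mode="json")


def write_registry(
    registry: Registry, path: Union[str, Path], format: str = "auto"
) -> None:
    """Write a registry; ``load_registry`` of the result is field-for-field identical."""
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    if format not in _FORMATS:
        raise RegistryFormatError(f"unknown registry format {format!r}")
    data = registry_to_mapping(registry)
    if format == "json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    elif format == "yaml":
        path.write_text(
            yaml.safe_dump(data, sort_keys=False, allow_unicode=True),
            encoding="utf-8",
        )
    else:
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=_CSV_COLUMNS)
        writer.writeheader()
        writer.writerow(
            {
                "record_type": "registry",
                "schema_version": registry.schema_version,
                "proportion_scale": registry.proportion_scale.value,
            }
        )
        for tool in data["tools"]:
            writer.writerow(
                {
                    "record_type": "tool",
                    "tool_id": tool["tool_id"],
                    "payload": json.dumps(tool),
                }
            )
        for study in data["studies"]:
            writer.writerow(
                {
                    "record_type": "study",
                    "tool_id": study["tool_id"],
                    "study_id": study["study_id"],
                    "payload": json.dumps(study),
                }
            )
        path.write_text(buf.getvalue(), encoding="utf-8")


def _proportion_bounds(scale: ProportionScale) -> tuple[float, float]:
    return (0.0, 1.0) if scale is ProportionScale.UNIT_INTERVAL else (0.0, 100.0)


def validate_registry(registry: Registry) -> list[ValidationFinding]:
    """Check semantic invariants; returns findings (empty list = clean).

    Errors mark records the grading engine cannot interpret faithfully;
    warnings mark missing optional fields the mixed-evidence resolver uses
    (sample size, publication year).
    """
    findings: list[ValidationFinding] = []

    def err(record_id: str, message: str) -> None:
        findings.append(
            ValidationFinding(severity="error", record_id=record_id, message=message)
        )

    def warn(record_id: str, message: str) -> None:
        findings.append(
            ValidationFinding(severity="warning", record_id=record_id, message=message)
        )

    graded_tools = {s.tool_id for s in registry.studies}
    for tool in registry.tools:
        if tool.tool_id not in graded_tools:
            warn(tool.tool_id, "tool has no evidence studies; it will be UNGRADED")

    lo, hi = _proportion_bounds(registry.proportion_scale)
    impact_aspects = {
        EvaluationAspect.POTENTIAL_EFFECT,
        EvaluationAspect.POST_IMPLEMENTATION_IMPACT,
    }
    for study in registry.studies:
        sid = study.study_id
        if study.is_primary and study.aspect is not EvaluationAspect.INTERNAL_VALIDATION:
            err(sid, "primary (development) study must have aspect internal_validation")
        if study.aspect in impact_aspects and study.outcome_category is None:
            err(
                sid,
                f"aspect {study.aspect.value} requires an outcome_category "
                "(clinical_effectiveness, healthcare_efficiency or patient_safety)",
            )
        if study.aspect not in impact_aspects and study.outcome_category is not None:
            err(sid, f"outcome_category must be absent for aspect {study.aspect.value}")
        if study.match.sample_size is None:
            warn(sid, "sample_size absent; mixed-evidence small-sample rule cannot apply")
        if study.year is None:
            warn(sid, "year absent; mixed-evidence recency tie-break cannot apply")
        for finding in study.findings:
            name = finding.measure_name.strip().lower().replace("-", "_").replace(" ", "_")
            if name in PROPORTION_MEASURES and not (lo <= finding.value <= hi):
                err(
                    sid,
                    f"{finding.measure_name}={finding.value} outside declared "
                    f"{registry.proportion_scale.value} range [{lo}, {hi}]",
                )
    return findings


def registry_json_schema() -> dict:
    """JSON Schema for the canonical registry document."""
    return Registry.model_json_schema()


def validate_corpus(
    tool: ToolProfile,
    studies: list[EvidenceStudy],
    proportion_scale: ProportionScale = ProportionScale.PERCENT,
) -> list[ValidationFinding]:
    """Semantic error findings restricted to one tool's corpus (used by batch grading)."""
    sub = Registry(tools=[tool], studies=studies, proportion_scale=proportion_scale)
    return [f for f in validate_registry(sub) if f.severity == "error"]
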