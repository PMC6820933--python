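"""The GRASP grading engine.

A predictive tool is graded along three dimensions:

* **Phase of evaluation** — C (predictive performance before implementation),
  B (usability and potential effect during implementation), A
  (post-implementation impact after real-world deployment).
* **Level of evidence** — a numeric level within each phase: C3 internal
  validation, C2 one external validation, C1 repeated external validation;
  B2 potential effect, B1 usability; A3 subjective/descriptive impact
  evidence, A2 observational, A1 experimental.
* **Direction of evidence** — positive when all studies at a level conclude
  positively, negative when all conclude negatively or equivocally, otherwise
  mixed and resolved by the mixed-evidence protocol.

The final grade is the highest level, scanning A1 → A2 → A3 → B1 → B2 → C1 →
C2 → C3, whose evidence resolves positive. The grade is a code identifying
that level, not an ordinal quality score; the scan order exists only to find
"highest".

Mixed-evidence protocol (the concrete rule, applied deterministically and
traced step by step):

1. demote by one quality tier any study whose sample size is below
   ``min_sample`` (very small samples weaken a study's standing);
2. restrict to studies fully matching the tool's original specification
   (target population, outcome, setting) when at least one exists;
3. within the restricted set, take the highest quality tier present and
   resolve by strict majority of positive vs negative+equivocal conclusions;
4. on a tie, widen cumulatively to the next tier and re-tally;
5. if still tied after all tiers, follow the more recent side (median
   publication year);
6. if still tied, resolve negative (conservative default).
"""

from __future__ import annotations

import enum
import statistics
from typing import Optional, Union

from pydantic import BaseModel, Field, field_validator

from .model import (
    ConclusionDirection,
    EvaluationAspect,
    EvidenceStudy,
    Registry,
    ToolProfile,
)
from .registry_io import validate_corpus

__all__ = [
    "PhaseLevel",
    "SCAN_ORDER",
    "RawDirection",
    "ResolutionConfig",
    "ResolutionStep",
    "DirectionResolution",
    "LevelEvidence",
    "GradeResult",
    "assign_levels",
    "determine_direction",
    "resolve_mixed",
    "final_grade",
    "grade_registry",
]


class PhaseLevel(str, enum.Enum):
    """Grade codes: phase letter + level digit, plus the C0 and UNGRADED sentinels."""

    A1 = "A1"
    A2 = "A2"
    A3 = "A3"
    B1 = "B1"
    B2 = "B2"
    C1 = "C1"
    C2 = "C2"
    C3 = "C3"
    C0 = "C0"
    UNGRADED = "UNGRADED"

    @property
    def phase(self) -> Optional[str]:
        return self.value[0] if self is not PhaseLevel.UNGRADED else None

    @property
    def level(self) -> Optional[int]:
        return int(self.value[1]) if self is not PhaseLevel.UNGRADED else None

    def rank(self) -> int:
        """Position in the scan order; larger = higher. Internal device only."""
        return _RANK[self]

    def is_above(self, other: "PhaseLevel") -> bool:
        return self.rank() > other.rank()


#: total scan order for "highest level of positive evidence"
SCAN_ORDER: tuple[PhaseLevel, ...] = (
    PhaseLevel.A1,
    PhaseLevel.A2,
    PhaseLevel.A3,
    PhaseLevel.B1,
    PhaseLevel.B2,
    PhaseLevel.C1,
    PhaseLevel.C2,
    PhaseLevel.C3,
)

_RANK = {
    level: rank
    for rank, level in enumerate(
        (PhaseLevel.UNGRADED, PhaseLevel.C0) + tuple(reversed(SCAN_ORDER))
    )
}


class RawDirection(str, enum.Enum):
    ALL_POSITIVE = "all_positive"
    ALL_NEGATIVE = "all_negative"
    MIXED = "mixed"


_TIE_BREAKS = ("cumulative_tier", "recency", "negative")


class ResolutionConfig(BaseModel):
    """Tunable constants of the grading engine.

    ``min_sample`` is the sample-size floor below which a study is demoted one
    quality tier during mixed-evidence resolution. ``tie_break_order`` lists
    the tie-break rules applied, in order, when the highest-tier tally is
    even; ``negative`` is always applied last regardless. ``enable_c0``
    switches on the C0 grade for tools whose internal validation was
    insufficient or insufficiently reported.
    """

    enable_c0: bool = True
    min_sample: int = Field(default=1000, ge=0)
    tie_break_order: tuple[str, ...] = ("cumulative_tier", "recency", "negative")

    @field_validator("tie_break_order")
    @classmethod
    def _known_rules(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        unknown = [rule for rule in v if rule not in _TIE_BREAKS]
        if unknown:
            raise ValueError(
                f"unknown tie-break rule(s) {unknown}; allowed: {list(_TIE_BREAKS)}"
            )
        return v


class ResolutionStep(BaseModel):
    """One traced step of the mixed-evidence protocol."""

    rule: str
    studies_considered: list[str]
    tally: dict[str, float] = Field(default_factory=dict)
    note: str = ""


class DirectionResolution(BaseModel):
    """Raw and resolved direction at one level, with the resolution trace."""

    raw_direction: RawDirection
    resolved_direction: ConclusionDirection
    resolution_trace: list[ResolutionStep] = Field(default_factory=list)


class LevelEvidence(BaseModel):
    """Evidence and its resolved direction at one phase/level."""

    level: PhaseLevel
    study_ids: list[str]
    resolution: DirectionResolution


class GradeResult(BaseModel):
    """Final grade plus the complete justification trace."""

    tool_id: str
    grade: PhaseLevel
    per_level_evidence: dict[str, LevelEvidence] = Field(default_factory=dict)
    justification: str = ""
    config: ResolutionConfig = Field(default_factory=ResolutionConfig)


class GradingError(Exception):
    """The corpus cannot be graded (contract violation or uninterpretable record)."""


_ASPECT_LEVEL = {
    EvaluationAspect.INTERNAL_VALIDATION: PhaseLevel.C3,
    EvaluationAspect.POTENTIAL_EFFECT: PhaseLevel.B2,
    EvaluationAspect.USABILITY: PhaseLevel.B1,
}

_TIER_TO_A = {1: PhaseLevel.A1, 2: PhaseLevel.A2, 3: PhaseLevel.A3}


def assign_levels(
    studies: list[EvidenceStudy],
) -> dict[PhaseLevel, list[EvidenceStudy]]:
    """Bucket one tool's studies by phase/level.

    Internal validations land at C3; external validations at C1 when the tool
    has been externally validated in two or more distinct publications, else
    C2; potential-effect studies at B2; usability studies at B1;
    post-implementation impact studies at A1/A2/A3 by design tier
    (experimental / observational / subjective-descriptive).
    """
    tool_ids = {s.tool_id for s in studies}
    if len(tool_ids) > 1:
        raise GradingError(f"studies span multiple tools: {sorted(tool_ids)}")
    buckets: dict[PhaseLevel, list[EvidenceStudy]] = {}
    external = [s for s in studies if s.aspect is EvaluationAspect.EXTERNAL_VALIDATION]
    n_external_pubs = len({s.citation or s.study_id for s in external})
    external_level = PhaseLevel.C1 if n_external_pubs >= 2 else PhaseLevel.C2
    for study in studies:
        if study.aspect is EvaluationAspect.EXTERNAL_VALIDATION:
            level = external_level
        elif study.aspect is EvaluationAspect.POST_IMPLEMENTATION_IMPACT:
            level = _TIER_TO_A[study.design.tier]
        elif study.aspect in _ASPECT_LEVEL:
            level = _ASPECT_LEVEL[study.aspect]
        else:  # pragma: no cover - schema drift guard
            raise GradingError(
                f"study {study.study_id}: unknown aspect {study.aspect!r}"
            )
        buckets.setdefault(level, []).append(study)
    return buckets


def _is_negative(direction: ConclusionDirection) -> bool:
    # equivocal conclusions aggregate with negative, never positive
    return direction in (ConclusionDirection.NEGATIVE, ConclusionDirection.EQUIVOCAL)


def determine_direction(studies: list[EvidenceStudy]) -> RawDirection:
    """Raw direction of a non-empty bucket of studies at one level."""
    if not studies:
        raise GradingError("determine_direction requires a non-empty study list")
    if all(s.direction is ConclusionDirection.POSITIVE for s in studies):
        return RawDirection.ALL_POSITIVE
    if all(_is_negative(s.direction) for s in studies):
        return RawDirection.ALL_NEGATIVE
    return RawDirection.MIXED


def _effective_tier(study: EvidenceStudy, config: ResolutionConfig) -> int:
    tier = study.design.tier
    size = study.match.sample_size
    if size is not None and size < config.min_sample:
        tier = min(3, tier + 1)
    return tier


def _tally(studies: list[EvidenceStudy]) -> tuple[int, int]:
    pos = sum(1 for s in studies if s.direction is ConclusionDirection.POSITIVE)
    return pos, len(studies) - pos


def resolve_mixed(
    studies: list[EvidenceStudy],
    tool_spec: ToolProfile,
    config: Optional[ResolutionConfig] = None,
) -> DirectionResolution:
    """Resolve a mixed-direction bucket to an overall positive or negative.

    See the module docstring for the protocol. Returns the resolved direction
    together with a step-by-step trace suitable for audit in the detailed
    report.
    """
    config = config or ResolutionConfig()
    raw = determine_direction(studies)
    if raw is not RawDirection.MIXED:
        raise GradingError("resolve_mixed called on a bucket that is not mixed")

    trace: list[ResolutionStep] = []

    demoted = [s.study_id for s in studies if _effective_tier(s, config) != s.design.tier]
    trace.append(
        ResolutionStep(
            rule="demote_small_samples",
            studies_considered=demoted,
            note=(
                f"studies with sample_size < {config.min_sample} demoted one quality tier"
                if demoted
                else f"no study below the sample-size floor of {config.min_sample}"
            ),
        )
    )

    matching = [s for s in studies if s.match.fully_matching]
    considered = matching if matching else list(studies)
    pos, neg = _tally(considered)
    trace.append(
        ResolutionStep(
            rule="restrict_to_matching",
            studies_considered=[s.study_id for s in considered],
            tally={"positive": pos, "negative_or_equivocal": neg},
            note=(
                "restricted to studies fully matching the tool's target "
                "population, outcome and setting"
                if matching
                else "no fully matching study; all studies retained"
            ),
        )
    )

    tiers_present = sorted({_effective_tier(s, config) for s in considered})

    def tally_tiers(upto_index: int) -> tuple[list[EvidenceStudy], int, int]:
        included = [
            s
            for s in considered
            if _effective_tier(s, config) in tiers_present[: upto_index + 1]
        ]
        p, n = _tally(included)
        return included, p, n

    included, pos, neg = tally_tiers(0)
    trace.append(
        ResolutionStep(
            rule=f"tally_highest_tier_{tiers_present[0]}",
            studies_considered=[s.study_id for s in included],
            tally={"positive": pos, "negative_or_equivocal": neg},
        )
    )
    if pos != neg:
        resolved = (
            ConclusionDirection.POSITIVE if pos > neg else ConclusionDirection.NEGATIVE
        )
        return DirectionResolution(
            raw_direction=raw, resolved_direction=resolved, resolution_trace=trace
        )

    resolved: Optional[ConclusionDirection] = None
    order = tuple(config.tie_break_order)
    if "negative" not in order:
        order = order + ("negative",)
    for rule in order:
        if rule == "cumulative_tier":
            for idx in range(1, len(tiers_present)):
                included, pos, neg = tally_tiers(idx)
                trace.append(
                    ResolutionStep(
                        rule=f"widen_to_tier_{tiers_present[idx]}",
                        studies_considered=[s.study_id for s in included],
                        tally={"positive": pos, "negative_or_equivocal": neg},
                    )
                )
                if pos != neg:
                    resolved = (
                        ConclusionDirection.POSITIVE
                        if pos > neg
                        else ConclusionDirection.NEGATIVE
                    )
                    break
        elif rule == "recency":
            pos_years = [
                s.year
                for s in considered
                if s.direction is ConclusionDirection.POSITIVE and s.year is not None
            ]
            neg_years = [
                s.year for s in considered if _is_negative(s.direction) and s.year is not None
            ]
            if pos_years and neg_years:
                pos_med = statistics.median(pos_years)
                neg_med = statistics.median(neg_years)
                trace.append(
                    ResolutionStep(
                        rule="recency",
                        studies_considered=[s.study_id for s in considered],
                        tally={
                            "positive_median_year": pos_med,
                            "negative_median_year": neg_med,
                        },
                        note="tie broken toward the more recent side",
                    )
                )
                if pos_med != neg_med:
                    resolved = (
                        ConclusionDirection.POSITIVE
                        if pos_med > neg_med
                        else ConclusionDirection.NEGATIVE
                    )
            else:
                trace.append(
                    ResolutionStep(
                        rule="recency",
                        studies_considered=[s.study_id for s in considered],
                        note="publication years unavailable; rule skipped",
                    )
                )
        elif rule == "negative":
            resolved = ConclusionDirection.NEGATIVE
            trace.append(
                ResolutionStep(
                    rule="default_negative",
                    studies_considered=[s.study_id for s in considered],
                    note="unresolvable tie defaults to negative",
                )
            )
        if resolved is not None:
            break
    assert resolved is not None
    return DirectionResolution(
        raw_direction=raw, resolved_direction=resolved, resolution_trace=trace
    )


def _resolve_bucket(
    studies: list[EvidenceStudy], tool: ToolProfile, config: ResolutionConfig
) -> DirectionResolution:
    raw = determine_direction(studies)
    if raw is RawDirection.MIXED:
        return resolve_mixed(studies, tool, config)
    resolved = (
        ConclusionDirection.POSITIVE
        if raw is RawDirection.ALL_POSITIVE
        else ConclusionDirection.NEGATIVE
    )
    return DirectionResolution(raw_direction=raw, resolved_direction=resolved)


def final_grade(
    tool: ToolProfile,
    studies: list[EvidenceStudy],
    config: Optional[ResolutionConfig] = None,
) -> GradeResult:
    """Grade one tool from its evidence corpus.

    Scans levels from A1 downward; the grade is the first level whose evidence
    resolves positive. A tool whose only evidence is an insufficient internal
    validation receives C0 (when enabled); a tool with no gradeable positive
    evidence and no internal validation is UNGRADED.
    """
    config = config or ResolutionConfig()
    if not studies:
        return GradeResult(
            tool_id=tool.tool_id,
            grade=PhaseLevel.UNGRADED,
            justification=(
                f"{tool.name}: no evidence studies in the registry; "
                "the tool cannot be graded."
            ),
            config=config,
        )

    buckets = assign_levels(studies)
    per_level: dict[str, LevelEvidence] = {}
    lines: list[str] = []
    grade: Optional[PhaseLevel] = None
    for level in SCAN_ORDER:
        if level not in buckets:
            continue
        bucket = buckets[level]
        resolution = _resolve_bucket(bucket, tool, config)
        per_level[level.value] = LevelEvidence(
            level=level,
            study_ids=[s.study_id for s in bucket],
            resolution=resolution,
        )
        n = len(bucket)
        if resolution.resolved_direction is ConclusionDirection.POSITIVE:
            qualifier = (
                "all positive"
                if resolution.raw_direction is RawDirection.ALL_POSITIVE
                else "mixed evidence resolved positive"
            )
            if grade is None:
                grade = level
                lines.append(
                    f"{level.value}: {n} study record(s), {qualifier} — "
                    f"highest positively supported level; grade assigned."
                )
            else:
                lines.append(
                    f"{level.value}: {n} study record(s), {qualifier} "
                    f"(below the assigned grade)."
                )
        else:
            qualifier = (
                "all negative or equivocal"
                if resolution.raw_direction is RawDirection.ALL_NEGATIVE
                else "mixed evidence resolved negative"
            )
            lines.append(
                f"{level.value}: {n} study record(s), {qualifier} — "
                "cannot support a grade."
            )

    if grade is None:
        has_internal = PhaseLevel.C3.value in per_level
        if has_internal and config.enable_c0:
            grade = PhaseLevel.C0
            lines.append(
                "C0: internal validation reported but insufficient or "
                "insufficiently positive; no level positively supported."
            )
        else:
            grade = PhaseLevel.UNGRADED
            lines.append("No level is positively supported; the tool is UNGRADED.")

    justification = "\n".join(lines)
    return GradeResult(
        tool_id=tool.tool_id,
        grade=grade,
        per_level_evidence=per_level,
        justification=justification,
        config=config,
    )


def grade_registry(
    registry: Registry, config: Optional[ResolutionConfig] = None
) -> list[GradeResult]:
    """Grade every tool in a registry, in registry order.

    A tool whose corpus fails semantic validation (or raises during grading)
    is reported as UNGRADED with the failure in its justification; the batch
    never aborts.
    """
    config = config or ResolutionConfig()
    results: list[GradeResult] = []
    for tool in registry.tools:
        studies = registry.studies_for(tool.tool_id)
        errors = validate_corpus(tool, studies, registry.proportion_scale)
        if errors:
            detail = "; ".join(f"{f.record_id}: {f.message}" for f in errors)
            results.append(
                GradeResult(
                    tool_id=tool.tool_id,
                    grade=PhaseLevel.UNGRADED,
                    justification=f"corpus failed validation — {detail}",
                    config=config,
                )
            )
            continue
        try:
            results.append(final_grade(tool, studies, config))
        except GradingError as exc:
            results.append(
                GradeResult(
                    tool_id=tool.tool_id,
                    grade=PhaseLevel.UNGRADED,
                    justification=f"grading failed — {exc}",
                    config=config,
                )
            )
    return results
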