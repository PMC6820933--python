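"""Registry data model for predictive tools and their published evaluation evidence.

A :class:`Registry` holds one :class:`ToolProfile` per predictive tool and one
:class:`EvidenceStudy` per (publication × evaluated aspect). A publication that
reports, say, both a usability arm and an external validation is entered as two
records sharing a citation, because the level of evidence is assigned per aspect.

Enumerated fields accept case-insensitive input (spaces and hyphens tolerated)
and are stored in canonical lower_snake form.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class RegistryError(Exception):
    """Base class for registry loading/validation failures."""


class RegistryFormatError(RegistryError):
    """The file could not be parsed in the requested format."""


class RegistryValidationError(RegistryError):
    """Parsed content violates the registry data model."""


class ReferentialIntegrityError(RegistryValidationError):
    """A study references a tool_id that does not exist in the registry."""


def _canon(value: str) -> str:
    return value.strip().lower().replace("-", "_").replace(" ", "_")


class _CanonEnum(str, enum.Enum):
    """str-Enum with case/separator-insensitive lookup."""

    @classmethod
    def _missing_(cls, value):
        if isinstance(value, str):
            canon = _canon(value)
            for member in cls:
                if member.value == canon:
                    return member
        allowed = ", ".join(m.value for m in cls)
        raise ValueError(f"{value!r} is not one of: {allowed}")


class EvaluationAspect(_CanonEnum):
    """What an evaluation study examined; exactly one aspect per record."""

    INTERNAL_VALIDATION = "internal_validation"
    EXTERNAL_VALIDATION = "external_validation"
    POTENTIAL_EFFECT = "potential_effect"
    USABILITY = "usability"
    POST_IMPLEMENTATION_IMPACT = "post_implementation_impact"


class StudyDesign(_CanonEnum):
    """Study design, each mapped to a quality tier (1 best)."""

    # tier 1 — experimental
    SYSTEMATIC_REVIEW_OF_TRIALS = "systematic_review_of_trials"
    RANDOMISED_CONTROLLED_TRIAL = "randomised_controlled_trial"
    NONRANDOMISED_CONTROLLED_TRIAL = "nonrandomised_controlled_trial"
    # tier 2 — observational
    COHORT = "cohort"
    CASE_CONTROL = "case_control"
    BEFORE_AFTER_OBSERVATIONAL = "before_after_observational"
    CROSS_SECTIONAL = "cross_sectional"
    # tier 2 — usability-specific (tier 1 only when embedded in a trial,
    # in which case the record is entered with the trial design)
    THINK_ALOUD = "think_aloud"
    NEAR_LIVE_SIMULATION = "near_live_simulation"
    USABILITY_SURVEY = "usability_survey"
    # tier 3 — subjective / descriptive
    EXPERT_OPINION = "expert_opinion"
    DESCRIPTIVE_REPORT = "descriptive_report"
    SURVEY = "survey"

    @property
    def tier(self) -> int:
        return DESIGN_TIER[self]


DESIGN_TIER: dict[StudyDesign, int] = {
    StudyDesign.SYSTEMATIC_REVIEW_OF_TRIALS: 1,
    StudyDesign.RANDOMISED_CONTROLLED_TRIAL: 1,
    StudyDesign.NONRANDOMISED_CONTROLLED_TRIAL: 1,
    StudyDesign.COHORT: 2,
    StudyDesign.CASE_CONTROL: 2,
    StudyDesign.BEFORE_AFTER_OBSERVATIONAL: 2,
    StudyDesign.CROSS_SECTIONAL: 2,
    StudyDesign.THINK_ALOUD: 2,
    StudyDesign.NEAR_LIVE_SIMULATION: 2,
    StudyDesign.USABILITY_SURVEY: 2,
    StudyDesign.EXPERT_OPINION: 3,
    StudyDesign.DESCRIPTIVE_REPORT: 3,
    StudyDesign.SURVEY: 3,
}


class ConclusionDirection(_CanonEnum):
    """Direction of a study's reported conclusion.

    Equivocal is stored distinctly so reports can display it faithfully; it
    aggregates with negative (never positive) when directions are tallied.
    """

    POSITIVE = "positive"
    NEGATIVE = "negative"
    EQUIVOCAL = "equivocal"


class OutcomeCategory(_CanonEnum):
    """Impact-measure category for potential-effect and post-implementation records."""

    CLINICAL_EFFECTIVENESS = "clinical_effectiveness"
    HEALTHCARE_EFFICIENCY = "healthcare_efficiency"
    PATIENT_SAFETY = "patient_safety"


class ProportionScale(_CanonEnum):
    """Registry-wide declaration of how proportion-like measures are expressed."""

    UNIT_INTERVAL = "unit_interval"
    PERCENT = "percent"


#: measure names treated as proportion-like for range validation
PROPORTION_MEASURES = frozenset(
    {"sensitivity", "specificity", "c_statistic", "c-statistic", "auc",
     "ppv", "npv", "accuracy"}
)


class ToolProfile(BaseModel):
    """Identifying and descriptive metadata of one predictive tool.

    ``target_population``, ``target_outcome`` and ``clinical_setting`` form the
    tool's original target specification, against which each evaluation study's
    degree of matching is assessed.
    """

    model_config = ConfigDict(validate_assignment=True)

    tool_id: str = Field(min_length=1)
    name: str = Field(min_length=1)
    authors: list[str] = Field(default_factory=list)
    year_published: int = Field(ge=1900, le=2100)
    intended_use: str = ""
    target_population: str = Field(min_length=1)
    target_outcome: str = Field(min_length=1)
    clinical_setting: str = Field(min_length=1)
    input_data_source: str = ""
    input_data_type: str = ""
    intended_user: str = ""
    recommended_action: str = ""
    local_context_notes: Optional[str] = None


class MatchProfile(BaseModel):
    """Degree of matching between a study and the tool's original specification."""

    population_match: bool
    outcome_match: bool
    setting_match: bool
    sample_size: Optional[int] = Field(default=None, ge=0)
    match_notes: str = ""

    @property
    def fully_matching(self) -> bool:
        return self.population_match and self.outcome_match and self.setting_match


class Finding(BaseModel):
    """One reported quantitative result of a study."""

    measure_name: str
    value: float
    units: str = ""
    comparator_note: Optional[str] = None


class EvidenceStudy(BaseModel):
    """One published evaluation of a tool, for a single aspect."""

    model_config = ConfigDict(validate_assignment=True)

    study_id: str = Field(min_length=1)
    tool_id: str = Field(min_length=1)
    citation: str = ""
    year: Optional[int] = Field(default=None, ge=1900, le=2100)
    is_primary: bool = False
    aspect: EvaluationAspect
    design: StudyDesign
    direction: ConclusionDirection
    match: MatchProfile
    outcome_category: Optional[OutcomeCategory] = None
    findings: list[Finding] = Field(default_factory=list)
    population_description: str = ""
    setting_description: str = ""
    conclusion_summary: str = ""
    comparator_note: Optional[str] = None
    roster_inferred: bool = False


class Registry(BaseModel):
    """A set of tools plus the evidence corpus evaluating them."""

    schema_version: str = "1.0"
    proportion_scale: ProportionScale = ProportionScale.PERCENT
    tools: list[ToolProfile] = Field(default_factory=list)
    studies: list[EvidenceStudy] = Field(default_factory=list)

    @model_validator(mode="after")
    def _referential_integrity(self) -> "Registry":
        tool_ids = [t.tool_id for t in self.tools]
        dupes = {t for t in tool_ids if tool_ids.count(t) > 1}
        if dupes:
            raise ValueError(f"duplicate tool_id(s): {sorted(dupes)}")
        study_ids = [s.study_id for s in self.studies]
        dupes = {s for s in study_ids if study_ids.count(s) > 1}
        if dupes:
            raise ValueError(f"duplicate study_id(s): {sorted(dupes)}")
        known = set(tool_ids)
        dangling = sorted({s.tool_id for s in self.studies} - known)
        if dangling:
            # raised through pydantic; load_registry re-raises as
            # ReferentialIntegrityError
            raise ValueError(f"dangling tool_id reference(s): {dangling}")
        return self

    def studies_for(self, tool_id: str) -> list[EvidenceStudy]:
        return [s for s in self.studies if s.tool_id == tool_id]

    def tool(self, tool_id: str) -> ToolProfile:
        for t in self.tools:
            if t.tool_id == tool_id:
                return t
        raise KeyError(tool_id)


class ValidationFinding(BaseModel):
    """One issue found by :func:`grasp.registry_io.validate_registry`."""

    severity: str  # "error" | "warning"
    record_id: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.severity.upper()}\t{self.record_id}\t{self.message}"
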