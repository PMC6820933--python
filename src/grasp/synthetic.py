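"""Seeded synthetic evidence corpora with planted ground-truth grades.

The generator works grade-first: it samples (or is told) the target grade for
each synthetic tool and then constructs an evidence corpus that the grading
rules imply that grade for — positive evidence up to the planted level, plus
optional distractor studies designed not to change the outcome:

* non-matching negatives — excluded by the resolver's restriction to studies
  matching the tool's original specification;
* small-sample negatives — matching, but below the sample-size floor, so the
  resolver demotes them one quality tier (or, at the lowest tier, they are
  simply outnumbered);
* equivocal studies — matching and same-tier, always strictly outnumbered by
  positives.

Because construction never consults the engine, planted-grade recovery is a
genuine test of the grading rules rather than of the generator.
"""

from __future__ import annotations

import random
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .engine import PhaseLevel
from .model import (
    ConclusionDirection,
    EvidenceStudy,
    Finding,
    MatchProfile,
    Registry,
    StudyDesign,
    ToolProfile,
)

__all__ = ["SyntheticSpec", "generate_synthetic"]

#: designs used for planted positive evidence at each impact tier
_TIER_DESIGNS = {
    1: (StudyDesign.RANDOMISED_CONTROLLED_TRIAL,
        StudyDesign.NONRANDOMISED_CONTROLLED_TRIAL,
        StudyDesign.SYSTEMATIC_REVIEW_OF_TRIALS),
    2: (StudyDesign.COHORT, StudyDesign.BEFORE_AFTER_OBSERVATIONAL,
        StudyDesign.CASE_CONTROL),
    3: (StudyDesign.DESCRIPTIVE_REPORT, StudyDesign.EXPERT_OPINION,
        StudyDesign.SURVEY),
}

_USABILITY_DESIGNS = (
    StudyDesign.THINK_ALOUD,
    StudyDesign.NEAR_LIVE_SIMULATION,
    StudyDesign.USABILITY_SURVEY,
)

_OUTCOME_CATEGORIES = ("clinical_effectiveness", "healthcare_efficiency", "patient_safety")


class SyntheticSpec(BaseModel):
    """Specification of a synthetic registry.

    ``planted_grades`` lists the target grade code per tool (length
    ``n_tools``). The three noise counts apply per tool; a tool planted
    UNGRADED must carry no studies, so nonzero noise there is a spec error.
    """

    seed: int
    n_tools: int = Field(ge=1)
    planted_grades: list[PhaseLevel]
    n_nonmatching: int = Field(default=0, ge=0)
    n_small_sample: int = Field(default=0, ge=0)
    n_equivocal: int = Field(default=0, ge=0)
    min_sample: int = Field(default=1000, ge=1)

    @model_validator(mode="after")
    def _consistent(self) -> "SyntheticSpec":
        if len(self.planted_grades) != self.n_tools:
            raise ValueError(
                f"planted_grades has {len(self.planted_grades)} entries "
                f"for n_tools={self.n_tools}"
            )
        noise = self.n_nonmatching + self.n_small_sample + self.n_equivocal
        if noise and PhaseLevel.UNGRADED in self.planted_grades:
            raise ValueError(
                "a tool planted UNGRADED has zero studies; "
                "nonzero noise counts are contradictory"
            )
        return self


class _Corpus:
    """Per-tool study builder with deterministic ids and rng-driven details."""

    def __init__(self, tool_id: str, rng: random.Random, min_sample: int):
        self.tool_id = tool_id
        self.rng = rng
        self.min_sample = min_sample
        self.studies: list[EvidenceStudy] = []
        self._counter = 0

    def _next_id(self) -> str:
        self._counter += 1
        return f"{self.tool_id}-s{self._counter:02d}"

    def add(
        self,
        aspect: str,
        design: StudyDesign,
        direction: str,
        *,
        matching: bool = True,
        small: bool = False,
        is_primary: bool = False,
        outcome_category: Optional[str] = None,
    ) -> None:
        sid = self._next_id()
        if small:
            size = self.rng.randrange(20, self.min_sample)
        else:
            size = self.rng.randrange(self.min_sample, 50 * self.min_sample)
        self.studies.append(
            EvidenceStudy(
                study_id=sid,
                tool_id=self.tool_id,
                citation=f"syn-cite-{sid}",
                year=self.rng.randrange(1995, 2020),
                is_primary=is_primary,
                aspect=aspect,
                design=design,
                direction=direction,
                match=MatchProfile(
                    population_match=matching,
                    outcome_match=True,
                    setting_match=True,
                    sample_size=size,
                    match_notes="" if matching else "synthetic non-matching subpopulation",
                ),
                outcome_category=outcome_category,
                findings=[
                    Finding(
                        measure_name="sensitivity",
                        value=round(self.rng.uniform(60.0, 99.0), 1),
                        units="%",
                    )
                ],
                population_description="synthetic study population",
                setting_description="synthetic clinical setting",
                conclusion_summary=f"synthetic {direction} conclusion",
            )
        )


def _build_corpus(
    corpus: _Corpus,
    grade: PhaseLevel,
    n_nonmatching: int,
    n_small: int,
    n_equivocal: int,
) -> None:
    rng = corpus.rng
    e, s, m = n_equivocal, n_small, n_nonmatching

    if grade is PhaseLevel.UNGRADED:
        return

    if grade is PhaseLevel.C0:
        # insufficient internal validation; every distractor is also
        # negative-or-equivocal, so no level can resolve positive
        corpus.add("internal_validation", StudyDesign.COHORT, "negative", is_primary=True)
        for _ in range(e):
            corpus.add("internal_validation", StudyDesign.COHORT, "equivocal")
        for _ in range(s):
            corpus.add("internal_validation", StudyDesign.COHORT, "negative", small=True)
        for _ in range(m):
            corpus.add("internal_validation", StudyDesign.COHORT, "negative", matching=False)
        return

    # development study with positive internal validation underpins every
    # other grade
    corpus.add("internal_validation", StudyDesign.COHORT, "positive", is_primary=True)

    if grade is PhaseLevel.C3:
        # distractors join the C3 bucket; positives must strictly outnumber
        # the matching same-tier equivocals
        for _ in range(e):
            corpus.add("internal_validation", StudyDesign.COHORT, "positive")
        for _ in range(e):
            corpus.add("internal_validation", StudyDesign.COHORT, "equivocal")
        for _ in range(s):
            corpus.add("internal_validation", StudyDesign.COHORT, "negative", small=True)
        for _ in range(m):
            corpus.add("internal_validation", StudyDesign.COHORT, "negative", matching=False)
        return

    if grade is PhaseLevel.C2:
        # exactly one external-validation publication; distractors must not
        # touch the external-validation bucket (a second publication would
        # move it to C1), so they land below, at C3
        corpus.add("external_validation", StudyDesign.COHORT, "positive")
        for _ in range(e):
            corpus.add("internal_validation", StudyDesign.COHORT, "equivocal")
        for _ in range(s):
            corpus.add("internal_validation", StudyDesign.COHORT, "negative", small=True)
        for _ in range(m):
            corpus.add("internal_validation", StudyDesign.COHORT, "negative", matching=False)
        return

    # C1 and everything above rests on repeated positive external validation
    n_ext = max(2, e + s + 1) if grade is PhaseLevel.C1 else 2
    for _ in range(n_ext):
        corpus.add("external_validation", StudyDesign.COHORT, "positive")

    if grade is PhaseLevel.C1:
        for _ in range(e):
            corpus.add("external_validation", StudyDesign.COHORT, "equivocal")
        for _ in range(s):
            corpus.add("external_validation", StudyDesign.COHORT, "negative", small=True)
        for _ in range(m):
            corpus.add("external_validation", StudyDesign.COHORT, "negative", matching=False)
        return

    def planted_bucket(aspect: str, designs: tuple[StudyDesign, ...],
                       tier3: bool, outcome: bool) -> None:
        cat = rng.choice(_OUTCOME_CATEGORIES) if outcome else None
        # at tier 3 a small-sample negative cannot be demoted below the
        # positives' tier, so positives must outnumber small negatives too
        n_pos = e + s + 1 if tier3 else e + 1
        for _ in range(n_pos):
            corpus.add(aspect, rng.choice(designs), "positive", outcome_category=cat)
        for _ in range(e):
            corpus.add(aspect, rng.choice(designs), "equivocal", outcome_category=cat)
        for _ in range(s):
            corpus.add(aspect, rng.choice(designs), "negative", small=True,
                       outcome_category=cat)
        for _ in range(m):
            corpus.add(aspect, rng.choice(designs), "negative", matching=False,
                       outcome_category=cat)

    if grade is PhaseLevel.B2:
        planted_bucket("potential_effect", _TIER_DESIGNS[2], tier3=False, outcome=True)
    elif grade is PhaseLevel.B1:
        planted_bucket("usability", _USABILITY_DESIGNS, tier3=False, outcome=False)
    elif grade is PhaseLevel.A3:
        planted_bucket("post_implementation_impact", _TIER_DESIGNS[3],
                       tier3=True, outcome=True)
    elif grade is PhaseLevel.A2:
        planted_bucket("post_implementation_impact", _TIER_DESIGNS[2],
                       tier3=False, outcome=True)
    elif grade is PhaseLevel.A1:
        planted_bucket("post_implementation_impact", _TIER_DESIGNS[1],
                       tier3=False, outcome=True)
    else:  # pragma: no cover
        raise ValueError(f"cannot construct evidence for grade {grade}")


def generate_synthetic(spec: SyntheticSpec) -> tuple[Registry, dict[str, PhaseLevel]]:
    """Generate a registry plus the mapping tool_id → planted grade.

    Identical specs yield byte-identical registries.
    """
    rng = random.Random(spec.seed)
    tools: list[ToolProfile] = []
    studies: list[EvidenceStudy] = []
    planted: dict[str, PhaseLevel] = {}
    for i, grade in enumerate(spec.planted_grades):
        tool_id = f"syn{i:03d}"
        tools.append(
            ToolProfile(
                tool_id=tool_id,
                name=f"Synthetic Predictive Tool {i:03d}",
                authors=["Synthetic A"],
                year_published=rng.randrange(1980, 2015),
                intended_use=rng.choice(
                    ["diagnostic decision support", "prognostic decision support"]
                ),
                target_population="synthetic adult population",
                target_outcome="synthetic clinical outcome",
                clinical_setting="synthetic care setting",
                input_data_source="clinical",
                input_data_type="synthetic variables",
                intended_user="clinicians",
                recommended_action="synthetic recommended action",
            )
        )
        corpus = _Corpus(tool_id, rng, spec.min_sample)
        _build_corpus(
            corpus, grade, spec.n_nonmatching, spec.n_small_sample, spec.n_equivocal
        )
        studies.extend(corpus.studies)
        planted[tool_id] = grade
    registry = Registry(
        schema_version="1.0",
        proportion_scale="percent",
        tools=tools,
        studies=studies,
    )
    return registry, planted
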