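import pytest

from grasp import ResolutionConfig, build_fixture, combined_registry
from grasp.model import (
    EvidenceStudy,
    MatchProfile,
    Registry,
    ToolProfile,
)


@pytest.fixture(scope="session")
def config():
    return ResolutionConfig()


@pytest.fixture(scope="session")
def lace():
    return build_fixture("lace")


@pytest.fixture(scope="session")
def centor():
    return build_fixture("centor")


@pytest.fixture(scope="session")
def wells():
    return build_fixture("wells")


@pytest.fixture(scope="session")
def mews():
    return build_fixture("mews")


@pytest.fixture(scope="session")
def ottawa():
    return build_fixture("ottawa")


@pytest.fixture(scope="session")
def five_tools():
    return combined_registry()


def make_tool(tool_id="tool", **kwargs) -> ToolProfile:
    defaults = dict(
        tool_id=tool_id,
        name="Example Risk Score",
        authors=["Doe J"],
        year_published=2005,
        intended_use="prognostic decision support",
        target_population="adult inpatients",
        target_outcome="30-day adverse event",
        clinical_setting="hospital ward",
    )
    defaults.update(kwargs)
    return ToolProfile(**defaults)


_STUDY_SEQ = {"n": 0}


def make_study(
    tool_id="tool",
    aspect="external_validation",
    design="cohort",
    direction="positive",
    matching=True,
    sample_size=5000,
    year=2010,
    **kwargs,
) -> EvidenceStudy:
    _STUDY_SEQ["n"] += 1
    defaults = dict(
        study_id=f"s{_STUDY_SEQ['n']:04d}",
        tool_id=tool_id,
        citation=f"cite-{_STUDY_SEQ['n']:04d}",
        year=year,
        aspect=aspect,
        design=design,
        direction=direction,
        match=MatchProfile(
            population_match=matching,
            outcome_match=True,
            setting_match=True,
            sample_size=sample_size,
        ),
    )
    defaults.update(kwargs)
    return EvidenceStudy(**defaults)


def make_registry(tool, studies) -> Registry:
    return Registry(
        schema_version="1.0",
        proportion_scale="percent",
        tools=[tool],
        studies=studies,
    )
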