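"""Packaged evidence corpora for the five worked predictive tools.

Each fixture is a registry holding one tool and its evidence roster: LACE
Index for Readmission, Centor Score for Streptococcal Pharyngitis, Wells'
Criteria for Pulmonary Embolism, the Modified Early Warning Score, and the
Ottawa Knee Rule. Rosters transcribe the narrated study corpora (designs,
directions, match status, named sample sizes and effect sizes); records whose
identity is not individually narrated are padded as positive external
validations and flagged ``roster_inferred``.
"""

from __future__ import annotations

import json
from importlib import resources

from .model import Registry

FIXTURE_NAMES = ("lace", "centor", "wells", "mews", "ottawa")


def build_fixture(tool_name: str) -> Registry:
    """Return the packaged registry for one of the five fixture tools."""
    name = tool_name.strip().lower()
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {tool_name!r}; expected one of {', '.join(FIXTURE_NAMES)}"
        )
    text = resources.files("grasp.data").joinpath(f"{name}.json").read_text("utf-8")
    return Registry.model_validate(json.loads(text))


def combined_registry() -> Registry:
    """All five fixture corpora merged into a single registry."""
    tools = []
    studies = []
    for name in FIXTURE_NAMES:
        reg = build_fixture(name)
        tools.extend(reg.tools)
        studies.extend(reg.studies)
    return Registry(
        schema_version="1.0",
        proportion_scale="percent",
        tools=tools,
        studies=studies,
    )
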