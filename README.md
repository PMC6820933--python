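# grasp

Evidence-based grading and assessment of clinical predictive tools.

Clinicians choosing among risk scores, prediction rules and other clinical
decision-support algorithms face a large and uneven evidence base: most tools
are internally validated, fewer are externally validated, and only a handful
have measured post-implementation impact on care. `grasp` implements the
GRASP framework (Grading and Assessment of Predictive tools): it takes a
structured registry of a tool's published evaluation studies and produces an
evidence-based grade plus a fully auditable detailed report.

The grade combines three dimensions:

* **Phase of evaluation** — C: predictive performance tested before
  implementation; B: usability and/or potential effect evaluated during
  implementation; A: post-implementation impact reported after deployment.
* **Level of evidence** — within phase C: C3 internal validation, C2 one
  external validation, C1 repeated external validation; within phase B:
  B2 potential effect, B1 usability; within phase A: A3
  subjective/descriptive studies, A2 observational studies, A1 experimental
  studies (RCTs, nonrandomised controlled trials and their systematic
  reviews). An optional C0 marks tools whose internal validation was
  insufficient.
* **Direction of evidence** — positive when all studies at a level conclude
  positively; negative when all are negative or equivocal; otherwise mixed,
  and resolved by a deterministic protocol that ranks studies by quality tier
  and by their degree of matching with the tool's original target population,
  outcome and setting.

The final grade is the highest level supported by positive (or
positively-resolved mixed) evidence, scanning A1 → A2 → A3 → B1 → B2 → C1 →
C2 → C3. The grade is a code, not an ordinal score: an A1 tool is not
declared "better" than an A2 tool.

## Worked example

The package ships the evidence corpora of five well-known predictive tools
(LACE Index, Centor Score, Wells' Criteria, MEWS, Ottawa Knee Rule) as
registry fixtures. Grading the combined registry:

```
$ grasp fixtures --out demo
$ grasp summary demo/combined.json
```

prints:

```
| Tool | Year | Intended use | Highest phase | Level | Direction of evidence | Final grade |
| --- | --- | --- | --- | --- | --- | --- |
| LACE Index for Readmission | 2010 | prognostic decision support | C | 1 | mixed evidence resolved positive | C1 |
| Centor Score for Streptococcal Pharyngitis | 1981 | diagnostic decision support | B | 1 | all positive | B1 |
| Wells' Criteria for Pulmonary Embolism | 1997 | diagnostic decision support | A | 2 | all positive | A2 |
| Modified Early Warning Score (MEWS) | 2001 | prognostic decision support | A | 2 | mixed evidence resolved positive | A2 |
| Ottawa Knee Rule | 1995 | diagnostic decision support | A | 1 | all positive | A1 |
```

Reading one row: the LACE Index has been externally validated repeatedly
(level C1) with conflicting conclusions — two large validations positive, two
small subpopulation studies negative — and the mixed-evidence protocol
resolves the conflict positive because the negative studies were small and
conducted outside the tool's target population; with no published usability
or impact evidence, its grade is C1. The Ottawa Knee Rule, by contrast, has
two positive nonrandomised controlled trials of post-implementation impact on
healthcare efficiency, the highest phase and level: grade A1.

`grasp report demo/combined.json --out reports` writes a detailed markdown
report per tool (tool information, every study at every level with designs,
populations, findings and directions, the final grade with its justification,
and an appendix with each mixed-evidence resolution trace) plus the summary
table. `grasp grade` emits one `tool_id<TAB>grade` line per tool for
pipelines; `grasp validate` checks a registry and exits nonzero on errors;
`grasp simulate` writes seeded synthetic corpora with known planted grades.

The same operations are available as a library:

```python
from grasp import combined_registry, grade_registry

for result in grade_registry(combined_registry()):
    print(result.tool_id, result.grade.value)
# lace C1 / centor B1 / wells A2 / mews A2 / ottawa A1
```

## Registry format

A registry (JSON canonical; YAML and flat CSV supported) holds one
`ToolProfile` per tool — including its original target specification — and
one `EvidenceStudy` per publication × evaluated aspect, with study design,
conclusion direction, match-to-specification flags, sample size and reported
findings. A JSON Schema ships at `src/grasp/data/registry.schema.json`.
See `docs/methods.md` for the grading rules, resolver constants and design
decisions.

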