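# Methods

## The grading model

`grasp` grades a clinical predictive tool from the published evidence
evaluating it, not from the tool's own outputs. The unit of evidence is one
record per publication × evaluated aspect; a single trial that reports both a
usability arm and an external validation is entered as two records sharing a
citation, because levels of evidence are assigned per aspect.

Aspects map to phase/level as follows:

| Aspect | Level | Notes |
| --- | --- | --- |
| internal_validation | C3 | development-time performance (discrimination, calibration) |
| external_validation | C2 / C1 | C1 when ≥ 2 distinct publications, else C2 |
| potential_effect | B2 | pre-implementation estimated impact, by outcome category |
| usability | B1 | think-aloud, near-live simulation, satisfaction surveys |
| post_implementation_impact | A3 / A2 / A1 | by design tier: subjective → A3, observational → A2, experimental → A1 |

Study designs carry a quality tier: tier 1 experimental (systematic reviews
of trials, randomised and nonrandomised controlled trials), tier 2
observational (cohort, case-control, before-after, cross-sectional, and the
usability-specific designs), tier 3 subjective/descriptive (expert opinion,
descriptive reports, surveys). A usability study embedded in a trial is
entered with the trial design and therefore ranks tier 1.

"Multiple" external validation means **≥ 2 distinct publications**, counted
by citation. This is the minimal reading of the one/multiple distinction and
the weakest rule consistent with the worked corpora, where every C1
assignment rests on at least two publications. A systematic review counts as
a single publication; its pooled constituents are not unpacked.

At each populated level the **direction of evidence** is: positive iff every
study concludes positively; negative iff every study concludes negatively or
equivocally (equivocal always aggregates with negative, though it is stored
and displayed distinctly); otherwise mixed.

The **final grade** is the first level in the scan order A1 → A2 → A3 → B1 →
B2 → C1 → C2 → C3 whose direction resolves positive. The scan order is an
internal device for locating "highest"; the emitted grade is a categorical
code. Phases are independent: a tool can earn A1 with no usability evidence
at all. If no level resolves positive but an internal validation exists, the
tool receives C0 (tested but insufficiently validated; config-switchable,
default on, since this grade entered the framework as a reviewer refinement);
with no evidence at all the result is UNGRADED. A negatively-resolved
external-validation level cannot support C1 *or* C2 — the scan falls through
to C3 — because C1/C2 describe the same aspect at different evidence volume.

## The mixed-evidence protocol

Heterogeneity of designs, outcome measures and subpopulations makes numeric
pooling of effect sizes meaningless here, so conflicting conclusions are
resolved qualitatively and deterministically:

1. **Small-sample demotion** — any study with `sample_size < min_sample`
   (default **1000**) is demoted one quality tier (tier 3 stays tier 3).
   This captures the recurring pattern of negative validations conducted on
   very small samples.
2. **Restriction to matching studies** — if at least one study fully matches
   the tool's original target population, outcome and setting, non-matching
   studies are set aside. A tool is not penalised for performing poorly in a
   subpopulation it was never built for.
3. **Highest-tier majority** — within the retained set, the highest quality
   tier present is tallied: strict majority of positive vs
   negative+equivocal decides.
4. **Cumulative widening** — on a tie, the next tier is folded in and the
   tally repeated.
5. **Recency** — if still tied, the side with the more recent median
   publication year wins.
6. **Negative default** — an unresolvable tie is negative.

Every step is recorded in a trace that the detailed report renders verbatim,
so end users can audit exactly how a conflict was resolved. The protocol is a
calibrated reconstruction (flagged as such in report provenance): the
constants and tie-break order are the weakest rule set that reproduces all
four worked resolutions in the packaged corpora — LACE external validity →
positive (small non-matching negatives set aside), MEWS external validity →
positive (sepsis-subpopulation negative set aside), MEWS post-implementation
impact → positive (3 v 1 observational majority), Centor post-implementation
impact → negative (1 v 3 tier-1 majority). `min_sample`, the tie-break order
and `enable_c0` are exposed in `ResolutionConfig` and echoed into every
report's provenance block.

Comparative-performance studies ("performed well but not better than the
comparator") are encoded `direction=positive` with a `comparator_note`,
because they affirm external validity; reports surface the note.

## Order properties and their one exception

Two properties are enforced over seeded synthetic corpora: **monotonicity**
(adding one positive, fully-matching study at a level strictly above the
current grade never lowers the grade) and **conservatism** (adding a negative
or equivocal study never raises it). Conservatism has exactly one structural
exception, which follows from the count-based C1/C2 split: adding a *second*
external-validation publication — whatever its direction — moves the
external-validation bucket from C2 to C1, a promotion by volume of evidence,
not by direction. When the added negative is then excluded by the matching
restriction, a C2 tool can emerge as C1. The property test carves out exactly
this case.

## Packaged fixtures

The five fixture registries transcribe the worked evidence corpora: 6 (LACE),
14 (Centor), 10 (Wells), 12 (MEWS) and 14 (Ottawa) evaluation records — 56 in
total — plus 7 primary development records (Wells carries three primary
studies; the other tools one each). Named quantities are encoded exactly
where reported: the LACE validation samples of 26 045 and 59 652 versus the
negative subpopulation studies of 507 (geriatric) and 253 (heart failure);
the Ottawa systematic review's pooled 4 249 adults and the 3 907-patient
impact trial; the Centor usability arms with 10 think-aloud and 8 near-live
providers; the 22 % reduction in antibiotic prescribing in the one positive
Centor impact RCT. Where the narrative does not identify individual studies
(11 of Ottawa's 14 evaluations), records are padded as positive external
validations and flagged `roster_inferred: true`. Publication years and sample
sizes not individually reported are plausible placeholders; none of them
influences any fixture grading (no fixture resolution reaches the recency
tie-break, and every demotion-relevant sample size is a reported one).

## Synthetic corpora

The generator is grade-first: given a planted grade it constructs positive
evidence up to exactly that level (a positive primary internal validation,
two positive external validations for grades at C1 and above, and a planted
bucket at the target level), then injects distractors designed not to change
the outcome — non-matching negatives (excluded by restriction), small-sample
negatives (demoted below the positives' tier, or outnumbered at tier 3), and
matching equivocals (always strictly outnumbered by positives). For a planted
C2 the distractors land at C3, since any second external-validation
publication would change the level by count. Corpora are deterministic under
the spec's seed, byte-for-byte.

What the generator does *not* emulate: real corpora with contradictory
evidence at several levels simultaneously, registries whose direction labels
are themselves contested (direction is taken as recorded by the appraiser),
and publication bias. Passing the recovery suite therefore shows the engine
implements the stated rules, not that the rules settle every real-world
corpus uncontroversially.

## Numerical and interface choices

* Proportion-like findings (sensitivity, specificity, c-statistic, …) are
  validated against a registry-wide scale declaration (`unit_interval` or
  `percent`), keeping range validation decidable.
* Equivocal is stored distinctly and collapsed only at tally time.
* Missing `sample_size` or `year` are warnings, not errors: the resolver
  simply skips the corresponding rule, and the validator tells the curator
  which resolver inputs are absent.
* Grading a registry is order-stable and per-tool isolated: a corpus that
  fails semantic validation yields UNGRADED with the failure in its
  justification, never an aborted batch.
* Reports are rendered deterministically (stable ordering, byte-identical
  for identical inputs) in markdown and JSON; the summary table additionally
  as CSV. Report sections run C → B → A, mirroring the before/during/after
  evaluation narrative, with the final grade and provenance last.
* Test problem sizes: the order-property and recovery suites each run 500+
  seeded corpora, and the resolver is checked exhaustively against a
  brute-force majority oracle over all 3^k direction assignments for
  fully-matching same-tier buckets of k ≤ 6 studies; the whole suite
  completes in a few seconds.

## Known limitations

* The mixed-evidence protocol is a reconstruction calibrated on four worked
  resolutions; other defensible rule sets exist. All constants are exposed
  in configuration and echoed in report provenance.
* Direction of evidence is taken as recorded by the appraiser; the package
  does not define a quantitative threshold separating positive from
  equivocal conclusions.
* No quality up/downgrading within a tier (risk-of-bias, inconsistency,
  imprecision) is applied; the tier of the study design is the whole quality
  signal.
* No meta-analysis: effect sizes are reported, never pooled, and grades of
  different tools are not ranked against each other.
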