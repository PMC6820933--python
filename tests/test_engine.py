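"""Level assignment, direction determination, mixed-evidence resolution and grading."""

import pytest

from conftest import make_registry, make_study, make_tool
from grasp.engine import (
    SCAN_ORDER,
    GradingError,
    PhaseLevel,
    RawDirection,
    ResolutionConfig,
    assign_levels,
    determine_direction,
    final_grade,
    grade_registry,
    resolve_mixed,
)
from grasp.model import ConclusionDirection, EvaluationAspect


def _bucket(registry, level):
    tool = registry.tools[0]
    return assign_levels(registry.studies_for(tool.tool_id))[level], tool


class TestScanOrder:
    def test_total_order_highest_first(self):
        assert [l.value for l in SCAN_ORDER] == [
            "A1", "A2", "A3", "B1", "B2", "C1", "C2", "C3"
        ]
        ranks = [l.rank() for l in SCAN_ORDER]
        assert ranks == sorted(ranks, reverse=True)
        assert PhaseLevel.C0.rank() < PhaseLevel.C3.rank()
        assert PhaseLevel.UNGRADED.rank() < PhaseLevel.C0.rank()

    def test_phase_and_level_components(self):
        assert PhaseLevel.A2.phase == "A" and PhaseLevel.A2.level == 2
        assert PhaseLevel.UNGRADED.phase is None


class TestAssignLevels:
    def test_ottawa_buckets(self, ottawa):
        buckets = assign_levels(ottawa.studies)
        assert set(buckets) == {PhaseLevel.C3, PhaseLevel.C1, PhaseLevel.A1}
        assert len(buckets[PhaseLevel.C1]) == 12
        assert len(buckets[PhaseLevel.A1]) == 2

    def test_single_external_validation_lands_at_c2(self):
        studies = [make_study(aspect="external_validation")]
        buckets = assign_levels(studies)
        assert set(buckets) == {PhaseLevel.C2}

    def test_two_records_of_one_publication_stay_at_c2(self):
        # a single publication entered twice is still one external validation
        a = make_study(aspect="external_validation", citation="same-pub")
        b = make_study(aspect="external_validation", citation="same-pub")
        assert set(assign_levels([a, b])) == {PhaseLevel.C2}

    def test_mews_impact_studies_all_in_a2(self, mews):
        buckets = assign_levels(mews.studies)
        impact = buckets[PhaseLevel.A2]
        assert len(impact) == 4
        assert all(
            s.aspect is EvaluationAspect.POST_IMPLEMENTATION_IMPACT for s in impact
        )

    def test_every_study_in_exactly_one_bucket(self, five_tools):
        for tool in five_tools.tools:
            studies = five_tools.studies_for(tool.tool_id)
            buckets = assign_levels(studies)
            bucketed = [s.study_id for b in buckets.values() for s in b]
            assert sorted(bucketed) == sorted(s.study_id for s in studies)

    def test_mixed_tool_ids_rejected(self):
        with pytest.raises(GradingError, match="multiple tools"):
            assign_levels([make_study(tool_id="a"), make_study(tool_id="b")])


class TestDetermineDirection:
    def test_wells_external_bucket_all_positive(self, wells):
        bucket, _ = _bucket(wells, PhaseLevel.C1)
        assert determine_direction(bucket) is RawDirection.ALL_POSITIVE

    def test_single_equivocal_counts_as_negative(self):
        assert (
            determine_direction([make_study(direction="equivocal")])
            is RawDirection.ALL_NEGATIVE
        )

    def test_centor_impact_bucket_is_mixed(self, centor):
        bucket, _ = _bucket(centor, PhaseLevel.A1)
        assert determine_direction(bucket) is RawDirection.MIXED

    def test_empty_bucket_is_contract_violation(self):
        with pytest.raises(GradingError):
            determine_direction([])


class TestResolveMixed:
    """The four narrated resolutions plus contract checks."""

    def test_lace_external_validity_resolves_positive(self, lace, config):
        bucket, tool = _bucket(lace, PhaseLevel.C1)
        res = resolve_mixed(bucket, tool, config)
        assert res.resolved_direction is ConclusionDirection.POSITIVE
        assert res.raw_direction is RawDirection.MIXED
        # the two small-sample subpopulation negatives are set aside by the
        # restriction to studies matching the original specification
        restrict = [s for s in res.resolution_trace if s.rule == "restrict_to_matching"]
        assert restrict and set(restrict[0].studies_considered) == {
            "lace-ev1", "lace-ev2", "lace-ev5", "lace-ev6"
        }

    def test_mews_external_validity_resolves_positive(self, mews, config):
        bucket, tool = _bucket(mews, PhaseLevel.C1)
        res = resolve_mixed(bucket, tool, config)
        assert res.resolved_direction is ConclusionDirection.POSITIVE
        restrict = [s for s in res.resolution_trace if s.rule == "restrict_to_matching"]
        assert "mews-ev8" not in restrict[0].studies_considered

    def test_mews_post_impact_resolves_positive(self, mews, config):
        bucket, tool = _bucket(mews, PhaseLevel.A2)
        res = resolve_mixed(bucket, tool, config)
        assert res.resolved_direction is ConclusionDirection.POSITIVE
        tallies = [s for s in res.resolution_trace if s.rule.startswith("tally_")]
        assert tallies[0].tally == {"positive": 3, "negative_or_equivocal": 1}

    def test_centor_post_impact_resolves_negative(self, centor, config):
        bucket, tool = _bucket(centor, PhaseLevel.A1)
        res = resolve_mixed(bucket, tool, config)
        assert res.resolved_direction is ConclusionDirection.NEGATIVE
        tallies = [s for s in res.resolution_trace if s.rule.startswith("tally_")]
        assert tallies[0].tally == {"positive": 1, "negative_or_equivocal": 3}

    def test_non_mixed_input_is_contract_violation(self, config):
        tool = make_tool()
        with pytest.raises(GradingError, match="not mixed"):
            resolve_mixed([make_study()], tool, config)

    def test_trace_nonempty_and_deterministic(self, lace, config):
        bucket, tool = _bucket(lace, PhaseLevel.C1)
        a = resolve_mixed(bucket, tool, config)
        b = resolve_mixed(bucket, tool, config)
        assert a == b
        assert a.resolution_trace

    def test_small_sample_demotion_changes_outcome(self, config):
        # two large negatives vs three small positives at the same tier:
        # without the floor the positives win 3-2; with it they are demoted
        # below the negatives' tier
        tool = make_tool()
        studies = [
            make_study(direction="negative", sample_size=5000),
            make_study(direction="negative", sample_size=5000),
            make_study(direction="positive", sample_size=120),
            make_study(direction="positive", sample_size=130),
            make_study(direction="positive", sample_size=140),
        ]
        res = resolve_mixed(studies, tool, config)
        assert res.resolved_direction is ConclusionDirection.NEGATIVE
        no_floor = ResolutionConfig(min_sample=0)
        res2 = resolve_mixed(studies, tool, no_floor)
        assert res2.resolved_direction is ConclusionDirection.POSITIVE

    def test_tie_widens_then_uses_recency(self, config):
        tool = make_tool()
        studies = [
            make_study(direction="positive", design="randomised_controlled_trial",
                       year=2018),
            make_study(direction="negative", design="randomised_controlled_trial",
                       year=2001),
        ]
        res = resolve_mixed(studies, tool, config)
        assert res.resolved_direction is ConclusionDirection.POSITIVE
        assert any(s.rule == "recency" for s in res.resolution_trace)

    def test_unresolvable_tie_defaults_negative(self, config):
        tool = make_tool()
        studies = [
            make_study(direction="positive", year=2010),
            make_study(direction="negative", year=2010),
        ]
        res = resolve_mixed(studies, tool, config)
        assert res.resolved_direction is ConclusionDirection.NEGATIVE
        assert res.resolution_trace[-1].rule == "default_negative"


class TestFinalGrade:
    @pytest.mark.parametrize(
        "fixture_name, expected",
        [
            ("lace", PhaseLevel.C1),
            ("centor", PhaseLevel.B1),
            ("wells", PhaseLevel.A2),
            ("mews", PhaseLevel.A2),
            ("ottawa", PhaseLevel.A1),
        ],
    )
    def test_fixture_grades(self, request, fixture_name, expected, config):
        registry = request.getfixturevalue(fixture_name)
        tool = registry.tools[0]
        result = final_grade(tool, registry.studies_for(tool.tool_id), config)
        assert result.grade is expected

    def test_grade_level_is_positive_and_higher_levels_negative(self, centor, config):
        tool = centor.tools[0]
        result = final_grade(tool, centor.studies, config)
        grade_ev = result.per_level_evidence[result.grade.value]
        assert grade_ev.resolution.resolved_direction is ConclusionDirection.POSITIVE
        for key, ev in result.per_level_evidence.items():
            if PhaseLevel(key).is_above(result.grade):
                assert (
                    ev.resolution.resolved_direction is ConclusionDirection.NEGATIVE
                )

    def test_single_positive_internal_validation_grades_c3(self, config):
        tool = make_tool()
        studies = [make_study(aspect="internal_validation", is_primary=True)]
        assert final_grade(tool, studies, config).grade is PhaseLevel.C3

    def test_zero_studies_is_ungraded_with_trace(self, config):
        result = final_grade(make_tool(), [], config)
        assert result.grade is PhaseLevel.UNGRADED
        assert "no evidence" in result.justification.lower()

    def test_insufficient_internal_validation_gets_c0(self):
        tool = make_tool()
        studies = [
            make_study(aspect="internal_validation", direction="negative",
                       is_primary=True)
        ]
        assert final_grade(tool, studies).grade is PhaseLevel.C0
        off = ResolutionConfig(enable_c0=False)
        assert final_grade(tool, studies, off).grade is PhaseLevel.UNGRADED

    def test_negative_external_validity_falls_through_to_c3(self, config):
        # negatively resolved external validation cannot support C1 or C2;
        # a positive internal validation still supports C3
        tool = make_tool()
        studies = [
            make_study(aspect="internal_validation", is_primary=True),
            make_study(aspect="external_validation", direction="negative"),
            make_study(aspect="external_validation", direction="negative"),
        ]
        assert final_grade(tool, studies, config).grade is PhaseLevel.C3

    def test_determinism(self, mews, config):
        tool = mews.tools[0]
        assert final_grade(tool, mews.studies, config) == final_grade(
            tool, mews.studies, config
        )


class TestGradeRegistry:
    def test_five_tool_registry_order_and_grades(self, five_tools, config):
        results = grade_registry(five_tools, config)
        assert [r.tool_id for r in results] == [
            "lace", "centor", "wells", "mews", "ottawa"
        ]
        assert [r.grade.value for r in results] == ["C1", "B1", "A2", "A2", "A1"]

    def test_empty_registry(self, config):
        from grasp.model import Registry

        assert grade_registry(Registry(), config) == []

    def test_malformed_corpus_does_not_abort_batch(self, five_tools, config):
        broken = five_tools.model_copy(deep=True)
        for study in broken.studies:
            if study.study_id == "wells-im1":
                study.outcome_category = None
        results = grade_registry(broken, config)
        by_id = {r.tool_id: r for r in results}
        assert by_id["wells"].grade is PhaseLevel.UNGRADED
        assert "outcome_category" in by_id["wells"].justification
        others = [by_id[t].grade.value for t in ("lace", "centor", "mews", "ottawa")]
        assert others == ["C1", "B1", "A2", "A1"]
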