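{
  "schema_version": "1.0",
  "proportion_scale": "percent",
  "tools": [
    {
      "tool_id": "lace",
      "name": "LACE Index for Readmission",
      "authors": [
        "van Walraven C"
      ],
      "year_published": 2010,
      "intended_use": "prognostic decision support",
      "target_population": "adult medical and surgical inpatients discharged to the community",
      "target_outcome": "30-day readmission or death after discharge",
      "clinical_setting": "hospital discharge, general inpatient care",
      "input_data_source": "administrative",
      "input_data_type": "length of stay, admission acuity, Charlson comorbidity index, ED visits in prior 6 months",
      "intended_user": "discharging clinicians and transitional-care teams",
      "recommended_action": "target transitional-care interventions at patients with high readmission risk",
      "local_context_notes": null
    }
  ],
  "studies": [
    {
      "study_id": "lace-p1",
      "tool_id": "lace",
      "citation": "Ref-125",
      "year": 2010,
      "is_primary": true,
      "aspect": "internal_validation",
      "design": "cohort",
      "direction": "positive",
      "match": {
        "population_match": true,
        "outcome_match": true,
        "setting_match": true,
        "sample_size": 4812,
        "match_notes": ""
      },
      "outcome_category": null,
      "findings": [
        {
          "measure_name": "c_statistic",
          "value": 68.4,
          "units": "%",
          "comparator_note": null
        }
      ],
      "population_description": "adult inpatients, 11 Ontario hospitals (derivation sample)",
      "setting_description": "Canadian community and academic hospitals",
      "conclusion_summary": "index discriminates 30-day readmission or death; internally validated via split-sample",
      "comparator_note": null,
      "roster_inferred": false
    },
    {
      "study_id": "lace-ev1",
      "tool_id": "lace",
      "citation": "Ref-129",
      "year": 2010,
      "is_primary": false,
      "aspect": "external_validation",
      "design": "cohort",
      "direction": "positive",
      "match": {
        "population_match": true,
        "outcome_match": true,
        "setting_match": true,
        "sample_size": 26045,
        "match_notes": ""
      },
      "outcome_category": null,
      "findings": [],
      "population_description": "adult medical inpatients, six hospitals in Toronto",
      "setting_description": "urban Canadian hospitals",
      "conclusion_summary": "positive external validity; superior to tools endorsed by the Centers for Medicare and Medicaid Services",
      "comparator_note": null,
      "roster_inferred": false
    },
    {
      "study_id": "lace-ev2",
      "tool_id": "lace",
      "citation": "Ref-130",
      "year": 2012,
      "is_primary": false,
      "aspect": "external_validation",
      "design": "cohort",
      "direction": "positive",
      "match": {
        "population_match": true,
        "outcome_match": true,
        "setting_match": true,
        "sample_size": 59652,
        "match_notes": ""
      },
      "outcome_category": null,
      "findings": [],
      "population_description": "adult inpatients, all hospitals in Alberta, Canada",
      "setting_description": "province-wide Canadian hospital network",
      "conclusion_summary": "positive external validity at provincial scale",
      "comparator_note": null,
      "roster_inferred": false
    },
    {
      "study_id": "lace-ev3",
      "tool_id": "lace",
      "citation": "Ref-131",
      "year": 2013,
      "is_primary": false,
      "aspect": "external_validation",
      "design": "cohort",
      "direction": "negative",
      "match": {
        "population_match": false,
        "outcome_match": true,
        "setting_match": true,
        "sample_size": 507,
        "match_notes": "geriatric subpopulation, different from the derivation population"
      },
      "outcome_category": null,
      "findings": [],
      "population_description": "507 geriatric patients in the United Kingdom",
      "setting_description": "UK geriatric medicine service",
      "conclusion_summary": "index performed poorly in an elderly subpopulation",
      "comparator_note": null,
      "roster_inferred": false
    },
    {
      "study_id": "lace-ev4",
      "tool_id": "lace",
      "citation": "Ref-132",
      "year": 2016,
      "is_primary": false,
      "aspect": "external_validation",
      "design": "cohort",
      "direction": "negative",
      "match": {
        "population_match": false,
        "outcome_match": true,
        "setting_match": true,
        "sample_size": 253,
        "match_notes": "congestive heart failure subpopulation"
      },
      "outcome_category": null,
      "findings": [],
      "population_description": "253 congestive heart failure patients in the United States",
      "setting_description": "US heart-failure service",
      "conclusion_summary": "index performed poorly in a heart-failure subpopulation",
      "comparator_note": null,
      "roster_inferred": false
    },
    {
      "study_id": "lace-ev5",
      "tool_id": "lace",
      "citation": "Ref-133",
      "year": 2015,
      "is_primary": false,
      "aspect": "external_validation",
      "design": "cohort",
      "direction": "positive",
      "match": {
        "population_match": true,
        "outcome_match": true,
        "setting_match": true,
        "sample_size": 1437,
        "match_notes": ""
      },
      "outcome_category": null,
      "findings": [],
      "population_description": "adult inpatients (comparative validation)",
      "setting_description": "hospital readmission programme",
      "conclusion_summary": "externally valid; compared against a locally developed readmission model",
      "comparator_note": "performed well but not better than the study's own newly developed tool",
      "roster_inferred": false
    },
    {
      "study_id": "lace-ev6",
      "tool_id": "lace",
      "citation": "Ref-134",
      "year": 2017,
      "is_primary": false,
      "aspect": "external_validation",
      "design": "cohort",
      "direction": "positive",
      "match": {
        "population_match": true,
        "outcome_match": true,
        "setting_match": true,
        "sample_size": 2165,
        "match_notes": ""
      },
      "outcome_category": null,
      "findings": [],
      "population_description": "adult inpatients (comparative validation)",
      "setting_description": "hospital readmission programme",
      "conclusion_summary": "externally valid; compared against a locally developed readmission model",
      "comparator_note": "performed well but not better than the study's own newly developed tool",
      "roster_inferred": false
    }
  ]
}
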