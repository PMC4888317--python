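# Clinical Data Report template (declarative, NON-NORMATIVE).
#
# A private structured-report template: a top-level Clinical Data Report
# container with demographic / risk-factor / diagnosis / treatment / outcome
# subordinate sections.  Rows: nesting level, relationship, value type,
# concept role (resolved through the terminology table), the clinical-record
# field the value comes from, requirement (M mandatory / U user option /
# C conditional), and for CODE rows a value set mapping record values to
# concept roles.  Concepts without a published standard code use the 99PQI
# private scheme (see terminology.yaml).
template_id: PQI_2000
rows:
  - {level: 0, value_type: CONTAINER, concept_role: clinical.report, requirement: M}
  - {level: 1, relationship: CONTAINS, value_type: CONTAINER, concept_role: clinical.demographics, requirement: M}
  - {level: 2, relationship: CONTAINS, value_type: CODE, concept_role: clinical.sex, field: sex, requirement: M,
     value_map: {M: clinical.sex.male, F: clinical.sex.female}}
  - {level: 2, relationship: CONTAINS, value_type: NUM, concept_role: clinical.age, field: age, requirement: M,
     units_role: units.year}
  - {level: 1, relationship: CONTAINS, value_type: CONTAINER, concept_role: clinical.risk_factors, requirement: U}
  - {level: 2, relationship: CONTAINS, value_type: CODE, concept_role: clinical.smoking, field: smoking, requirement: U,
     value_map: {"yes": clinical.yes, "no": clinical.no}}
  - {level: 2, relationship: CONTAINS, value_type: CODE, concept_role: clinical.alcohol, field: alcohol, requirement: U,
     value_map: {"yes": clinical.yes, "no": clinical.no}}
  - {level: 1, relationship: CONTAINS, value_type: CONTAINER, concept_role: clinical.diagnosis, requirement: M}
  - {level: 2, relationship: CONTAINS, value_type: TEXT, concept_role: clinical.pathology, field: pathology, requirement: M}
  - {level: 2, relationship: CONTAINS, value_type: TEXT, concept_role: clinical.stage, field: stage, requirement: U}
  - {level: 2, relationship: CONTAINS, value_type: TEXT, concept_role: clinical.primary_site, field: primary_site, requirement: U}
  - {level: 2, relationship: CONTAINS, value_type: TEXT, concept_role: clinical.nodal_sites, field: nodal_sites, requirement: U}
  - {level: 1, relationship: CONTAINS, value_type: CONTAINER, concept_role: clinical.treatment, requirement: U}
  - {level: 2, relationship: CONTAINS, value_type: CODE, concept_role: clinical.surgery, field: surgery, requirement: U,
     value_map: {"yes": clinical.yes, "no": clinical.no}}
  - {level: 2, relationship: CONTAINS, value_type: NUM, concept_role: clinical.radiation_dose, field: radiation_dose_gy,
     requirement: U, units_role: units.gy}
  - {level: 2, relationship: CONTAINS, value_type: CODE, concept_role: clinical.chemotherapy, field: chemotherapy, requirement: U,
     value_map: {"yes": clinical.yes, "no": clinical.no}}
  - {level: 1, relationship: CONTAINS, value_type: CONTAINER, concept_role: clinical.outcome, requirement: M}
  - {level: 2, relationship: CONTAINS, value_type: DATETIME, concept_role: clinical.followup_date, field: followup_date, requirement: M}
  - {level: 2, relationship: CONTAINS, value_type: CODE, concept_role: clinical.status, field: status, requirement: M,
     value_map: {alive: clinical.status.alive, dead: clinical.status.dead}}
  - {level: 2, relationship: CONTAINS, value_type: DATETIME, concept_role: clinical.death_date, field: death_date, requirement: C}
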