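# Consolidated NAIIS 2018/19 database assessment: the scores awarded by the
# independent monitors against the naiis-dqas rubric. Total 78/81 (96.3%,
# "Exceptional"); the only deductions are DESR (2/3) and DTI (2/4).
rubric_name: naiis-dqas
metadata:
  assessor: NAIIS independent monitors (consolidated)
  period: 2018-12 to 2019-04
scores:
  desr: 2
  personnel_training: 1
  personnel_certification: 1
  troubleshooting_session: 1
  troubleshooting_frequency: 3
  dm_supervisor: 1
  dm_deputy_supervisor: 1
  dm_qualification: 3
  dm_supervisor_qualification: 3
  db_knowledge_assessment: 3
  database_type: 1
  database_selection_justification: 1
  architecture_framework_concordance: 1
  database_complexity: 1
  prevalence_concordance: 5
  weighting_consideration: 1
  weighting_justification: 3
  weighting_appropriateness: 3
  backup_transfer_systems: 1
  database_dictionary: 1
  audit_system: 1
  inbuilt_checks: 1
  alert_inactivation: 1
  additional_audit_systems: 1
  double_key_entry: 1
  vmr: 4
  omr: 4
  duplicate_ratio: 1
  dictionary_quality: 8
  dsmb_presence: 1
  dsmb_membership: 3
  security_risk_management: 12
  external_monitors: 1
  dti: 2
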