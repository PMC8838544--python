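# Canonical dQAS rubric as applied to the NAIIS (Nigeria AIDS Indicator and
# Impact Survey, 2018) database: 34 items in 5 superordinate categories,
# maximum total 81.
#
# Per-item maxima: every judgment item's maximum equals the score the NAIIS
# database achieved (it attained full marks on all items except two); the two
# exceptions are the data-entry-sample ratio (DESR, maximum 3, NAIIS scored 2)
# and the Database Transparency Index (DTI, maximum 4, NAIIS scored 2). This
# reconstruction reproduces the published category maxima 38/5/9/8/21 exactly.
name: naiis-dqas
version: "1.0"
declared_max_total: 81
categories:
  - category_id: data_validity
    label: Data validity
    declared_max_subtotal: 38
    items:
      - item_id: desr
        label: Data-entry-sample ratio (DESR)
        max_score: 3
        description: >-
          Data-management personnel per 1000 records entered per day; higher
          implies greater staffing adequacy and a lower expected error rate.
      - item_id: personnel_training
        label: Data entry/management personnel training
        max_score: 1
      - item_id: personnel_certification
        label: Data entry/management personnel certification
        max_score: 1
      - item_id: troubleshooting_session
        label: Data entry/management personnel troubleshooting session
        max_score: 1
      - item_id: troubleshooting_frequency
        label: Frequency of troubleshooting sessions
        max_score: 3
      - item_id: dm_supervisor
        label: Presence of a data management supervisor
        max_score: 1
      - item_id: dm_deputy_supervisor
        label: Presence of a data management deputy supervisor
        max_score: 1
      - item_id: dm_qualification
        label: Qualification of data managers
        max_score: 3
      - item_id: dm_supervisor_qualification
        label: Qualification of the data manager supervisor
        max_score: 3
      - item_id: db_knowledge_assessment
        label: Data entry personnel/manager's database knowledge assessment
        max_score: 3
      - item_id: database_type
        label: Type of database
        max_score: 1
      - item_id: database_selection_justification
        label: Database selection justification
        max_score: 1
      - item_id: architecture_framework_concordance
        label: Architecture of database corresponding with the working conceptual framework
        max_score: 1
      - item_id: database_complexity
        label: Database degree of complexity
        max_score: 1
      - item_id: prevalence_concordance
        label: Concordance of prevalence estimates
        max_score: 5
      - item_id: weighting_consideration
        label: Weighting algorithm consideration
        max_score: 1
      - item_id: weighting_justification
        label: Justification of the weighting process
        max_score: 3
      - item_id: weighting_appropriateness
        label: Appropriateness of the weighting algorithm
        max_score: 3
      - item_id: backup_transfer_systems
        label: Files backup and transfer systems
        max_score: 1
      - item_id: database_dictionary
        label: Database dictionary creation
        max_score: 1
  - category_id: database_reliability
    label: Database reliability
    declared_max_subtotal: 5
    items:
      - item_id: audit_system
        label: Presence of data audit system
        max_score: 1
      - item_id: inbuilt_checks
        label: Presence of in-built checks mechanism
        max_score: 1
      - item_id: alert_inactivation
        label: Presence of alert or inactivation system
        max_score: 1
      - item_id: additional_audit_systems
        label: Presence of additional audit systems
        max_score: 1
      - item_id: double_key_entry
        label: Employment of a double key data entry validation process
        max_score: 1
  - category_id: database_precision
    label: Database precision
    declared_max_subtotal: 9
    items:
      - item_id: vmr
        label: Variable missing ratio (VMR)
        max_score: 4
        description: Missingness summarized over variables (columns) of the export.
      - item_id: omr
        label: Observation missing ratio (OMR)
        max_score: 4
        description: Missingness summarized over observations (rows) of the export.
      - item_id: duplicate_ratio
        label: Duplicate ratio
        max_score: 1
        description: Fraction of records that are exact copies of earlier records.
  - category_id: timeliness
    label: Timeliness
    declared_max_subtotal: 8
    items:
      - item_id: dictionary_quality
        label: Quality assessment of the database dictionary
        max_score: 8
  - category_id: database_integrity
    label: Database integrity
    declared_max_subtotal: 21
    items:
      - item_id: dsmb_presence
        label: Presence of a data and safety monitoring board (DSMB)
        max_score: 1
      - item_id: dsmb_membership
        label: Description of DSMB membership and expertise of members
        max_score: 3
      - item_id: security_risk_management
        label: Database security and risk management procedures
        max_score: 12
      - item_id: external_monitors
        label: Presence of external independent monitors
        max_score: 1
      - item_id: dti
        label: Database Transparency Index (DTI)
        max_score: 4
        description: >-
          Extent of database access granted to independent assessors.
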