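code_sets:
  copd_icd:
    - {vocab: ICD10, pattern: "J44", match: prefix}
  asthma_icd:
    - {vocab: ICD10, pattern: "J45", match: prefix}
  copd_rx:
    - {vocab: CUSTOM, pattern: "RX_TIO", match: exact}
  sodium:
    - {vocab: CUSTOM, pattern: "NA_BLOOD", match: exact}
  statin_rx:
    - {vocab: CUSTOM, pattern: "RX_STATIN", match: exact}
  ldl:
    - {vocab: CUSTOM, pattern: "LDL", match: exact}
phenotypes:
  - phenotype_id: CMP_RESP
    kind: binary
    category: respiratory
    case_rule:
      any:
        - {code_set: copd_rx, source: prescription, min_count: 2}
        - {code_set: copd_icd, source: hospital, min_count: 1}
    control_exclusion_rule:
      any:
        - {code_set: asthma_icd, min_count: 1}
  - phenotype_id: SODIUM
    kind: quantitative
    category: biochemistry
    quantitative_spec:
      code_set: sodium
      aggregation: mean
      min_measurements: 2
      plausible_range: [100, 200]
  - phenotype_id: LDL_STATIN_DELTA
    kind: quantitative
    category: drug_response
    drug_response:
      rx_code_set: statin_rx
      measure_code_set: ldl
      pre_window_days: 365
      post_lag_days: 30
      post_end_days: 365
  - phenotype_id: CMP_RESP_ONSET
    kind: quantitative
    category: progression
    age_of_onset_of: CMP_RESP
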