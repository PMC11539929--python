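# Illustrative Charlson Comorbidity Index mapping (Quan-style ICD-9/ICD-10
# prefixes with original Charlson weights). Ships for demonstration and
# testing only; the mapping version used in a real analysis is configuration.
conditions:
  - label: myocardial_infarction
    weight: 1
    codes:
      - {system: ICD9, code: "410", prefix: true}
      - {system: ICD9, code: "412"}
      - {system: ICD10, code: "I21", prefix: true}
      - {system: ICD10, code: "I22", prefix: true}
  - label: congestive_heart_failure
    weight: 1
    codes:
      - {system: ICD9, code: "428", prefix: true}
      - {system: ICD10, code: "I50", prefix: true}
  - label: peripheral_vascular_disease
    weight: 1
    codes:
      - {system: ICD9, code: "443.9"}
      - {system: ICD10, code: "I73.9"}
  - label: cerebrovascular_disease
    weight: 1
    codes:
      - {system: ICD9, code: "434", prefix: true}
      - {system: ICD10, code: "I63", prefix: true}
  - label: dementia
    weight: 1
    codes:
      - {system: ICD9, code: "290", prefix: true}
      - {system: ICD10, code: "F01", prefix: true}
      - {system: ICD10, code: "F02", prefix: true}
      - {system: ICD10, code: "F03", prefix: true}
  - label: chronic_pulmonary_disease
    weight: 1
    codes:
      - {system: ICD9, code: "496"}
      - {system: ICD10, code: "J44", prefix: true}
  - label: diabetes
    weight: 1
    codes:
      - {system: ICD9, code: "250.0", prefix: true}
      - {system: ICD10, code: "E11.9"}
  - label: diabetes_with_complications
    weight: 2
    codes:
      - {system: ICD9, code: "250.4", prefix: true}
      - {system: ICD10, code: "E11.2", prefix: true}
  - label: renal_disease
    weight: 2
    codes:
      - {system: ICD9, code: "585", prefix: true}
      - {system: ICD10, code: "N18", prefix: true}
  - label: any_malignancy
    weight: 2
    codes:
      - {system: ICD9, code: "174", prefix: true}
      - {system: ICD10, code: "C50", prefix: true}
  - label: metastatic_solid_tumor
    weight: 6
    codes:
      - {system: ICD9, code: "197", prefix: true}
      - {system: ICD10, code: "C78", prefix: true}
hierarchy:
  - {milder: diabetes, severer: diabetes_with_complications}
  - {milder: any_malignancy, severer: metastatic_solid_tumor}
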