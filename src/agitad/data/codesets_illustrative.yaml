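# Illustrative phenotype code sets for demonstration and testing only.
# A real claims analysis must supply its own clinically vetted ICD-9-CM /
# ICD-10-CM lists through this same configuration format; these entries are
# plausible but NOT authoritative.
AD:
  - {system: ICD9, code: "331.0"}
  - {system: ICD10, code: "G30", prefix: true}
dementia:
  - {system: ICD9, code: "290", prefix: true}
  - {system: ICD9, code: "294.1", prefix: true}
  - {system: ICD10, code: "F01", prefix: true}
  - {system: ICD10, code: "F02", prefix: true}
  - {system: ICD10, code: "F03", prefix: true}
agitation:
  - {system: ICD9, code: "307.9"}
  - {system: ICD9, code: "312.35"}
  - {system: ICD10, code: "R45.1", prefix: true}
  - {system: ICD10, code: "R45.5", prefix: true}
  - {system: ICD10, code: "R45.6", prefix: true}
  - {system: ICD10, code: "R46.3", prefix: true}
bipolar:
  - {system: ICD9, code: "296.0", prefix: true}
  - {system: ICD9, code: "296.1", prefix: true}
  - {system: ICD9, code: "296.4", prefix: true}
  - {system: ICD9, code: "296.5", prefix: true}
  - {system: ICD9, code: "296.6", prefix: true}
  - {system: ICD9, code: "296.7"}
  - {system: ICD10, code: "F31", prefix: true}
MDD:
  - {system: ICD9, code: "296.2", prefix: true}
  - {system: ICD9, code: "296.3", prefix: true}
  - {system: ICD10, code: "F32", prefix: true}
  - {system: ICD10, code: "F33", prefix: true}
schizophrenia:
  - {system: ICD9, code: "295", prefix: true}
  - {system: ICD10, code: "F20", prefix: true}
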