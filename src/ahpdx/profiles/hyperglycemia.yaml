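# Hyperglycemia condition profile: four risk factors weighted by AHP
# pairwise judgments (HDL moderately more important than LDL, both far
# more important than triglycerides and age; triglycerides and age equal).
# HDL activates when above its sex-specific bound, LDL when below 80 mg/dL.
condition: hyperglycemia
factors:
  - id: HDL
    name: HDL cholesterol
    category: elementary
    source: lab_analyte
    units: mg/dL
  - id: LDL
    name: LDL cholesterol
    category: elementary
    source: lab_analyte
    units: mg/dL
  - id: Triglyceridea
    name: Triglycerides
    category: elementary
    source: lab_analyte
    units: mg/dL
  - id: Age
    name: Age
    category: secondary
    source: demographic
    units: years
judgments:
  - [HDL, LDL, 3/1]
  - [HDL, Triglyceridea, 7/1]
  - [HDL, Age, 7/1]
  - [LDL, Triglyceridea, 5/1]
  - [LDL, Age, 5/1]
  - [Triglyceridea, Age, 1/1]
ranges:
  - {factor_id: HDL, sex: male, high: 40}
  - {factor_id: HDL, sex: female, high: 50}
  - {factor_id: LDL, sex: any, low: 80}
  - {factor_id: Triglyceridea, sex: any, high: 150}
  - {factor_id: Age, sex: any, high: 45}
diagnosis_threshold: 80
critical_threshold: 95
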