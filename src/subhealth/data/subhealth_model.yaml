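# Default five-construct subhealth physical-examination path model.
# Indicator order is meaningful: weights and loadings are reported in it.
constructs:
  - name: routine_blood_test
    mode: reflective
    indicators: [HGB, MCHC, RBC, HCT]
  - name: lipid_metabolism
    mode: reflective
    indicators: [TC, TG, LDL]
  - name: liver_function
    mode: reflective
    indicators: [AKP, ALT, AST, GGT]
  - name: sv_characteristics
    mode: reflective
    indicators: [SV-L, SV-a, SV-b]
  - name: obesity
    mode: formative
    indicators: [BMI, WHR]
paths:
  - [routine_blood_test, sv_characteristics]
  - [routine_blood_test, lipid_metabolism]
  - [obesity, sv_characteristics]
  - [lipid_metabolism, obesity]
  - [liver_function, sv_characteristics]
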