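name,label,low,high
ascvd_diabetes_ckd,Clinical ASCVD + diabetes with CKD,28,43
ascvd_diabetes_no_ckd,Clinical ASCVD + diabetes without CKD,26,29
ascvd_ckd,Clinical ASCVD + CKD,34,35
recent_acs,Recent ACS (< 3 months; within past year in this cohort),32,32
cad_poor_risk_control,CAD + poorly controlled risk factors,28,41
cad_pad,CAD + peripheral artery disease,43,55
cad_age_ge_65,CAD + age >= 65 years,21,54
stroke_tia_male,Ischemic stroke/TIA in a man,31,31
cad_fh,CAD + familial hypercholesterolemia (LDL-c >= 190 mg/dL),41,41
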