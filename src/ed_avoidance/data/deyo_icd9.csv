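category,pattern,match_type
myocardial_infarction,410,prefix
myocardial_infarction,412,prefix
congestive_heart_failure,428,prefix
peripheral_vascular_disease,441,prefix
peripheral_vascular_disease,4439,prefix
peripheral_vascular_disease,7854,prefix
peripheral_vascular_disease,V434,prefix
cerebrovascular_disease,430,prefix
cerebrovascular_disease,431,prefix
cerebrovascular_disease,432,prefix
cerebrovascular_disease,433,prefix
cerebrovascular_disease,434,prefix
cerebrovascular_disease,435,prefix
cerebrovascular_disease,436,prefix
cerebrovascular_disease,437,prefix
cerebrovascular_disease,438,prefix
dementia,290,prefix
chronic_pulmonary_disease,490,prefix
chronic_pulmonary_disease,491,prefix
chronic_pulmonary_disease,492,prefix
chronic_pulmonary_disease,493,prefix
chronic_pulmonary_disease,494,prefix
chronic_pulmonary_disease,495,prefix
chronic_pulmonary_disease,496,prefix
chronic_pulmonary_disease,500,prefix
chronic_pulmonary_disease,501,prefix
chronic_pulmonary_disease,502,prefix
chronic_pulmonary_disease,503,prefix
chronic_pulmonary_disease,504,prefix
chronic_pulmonary_disease,505,prefix
chronic_pulmonary_disease,5064,prefix
rheumatologic_disease,7100,prefix
rheumatologic_disease,7101,prefix
rheumatologic_disease,7104,prefix
rheumatologic_disease,7140,prefix
rheumatologic_disease,7141,prefix
rheumatologic_disease,7142,prefix
rheumatologic_disease,71481,prefix
rheumatologic_disease,725,prefix
peptic_ulcer_disease,531,prefix
peptic_ulcer_disease,532,prefix
peptic_ulcer_disease,533,prefix
peptic_ulcer_disease,534,prefix
mild_liver_disease,5712,prefix
mild_liver_disease,5714,prefix
mild_liver_disease,5715,prefix
mild_liver_disease,5716,prefix
diabetes,2500,prefix
diabetes,2501,prefix
diabetes,2502,prefix
diabetes,2503,prefix
diabetes,2507,prefix
diabetes_with_complications,2504,prefix
diabetes_with_complications,2505,prefix
diabetes_with_complications,2506,prefix
hemiplegia_paraplegia,342,prefix
hemiplegia_paraplegia,3441,prefix
renal_disease,582,prefix
renal_disease,5830,prefix
renal_disease,5831,prefix
renal_disease,5832,prefix
renal_disease,5833,prefix
renal_disease,5834,prefix
renal_disease,5835,prefix
renal_disease,5836,prefix
renal_disease,5837,prefix
renal_disease,585,prefix
renal_disease,586,prefix
renal_disease,588,prefix
malignancy,140,prefix
malignancy,141,prefix
malignancy,142,prefix
malignancy,143,prefix
malignancy,144,prefix
malignancy,145,prefix
malignancy,146,prefix
malignancy,147,prefix
malignancy,148,prefix
malignancy,149,prefix
malignancy,150,prefix
malignancy,151,prefix
malignancy,152,prefix
malignancy,153,prefix
malignancy,154,prefix
malignancy,155,prefix
malignancy,156,prefix
malignancy,157,prefix
malignancy,158,prefix
malignancy,159,prefix
malignancy,160,prefix
malignancy,161,prefix
malignancy,162,prefix
malignancy,163,prefix
malignancy,164,prefix
malignancy,165,prefix
malignancy,166,prefix
malignancy,167,prefix
malignancy,168,prefix
malignancy,169,prefix
malignancy,170,prefix
malignancy,171,prefix
malignancy,172,prefix
malignancy,174,prefix
malignancy,175,prefix
malignancy,176,prefix
malignancy,177,prefix
malignancy,178,prefix
malignancy,179,prefix
malignancy,180,prefix
malignancy,181,prefix
malignancy,182,prefix
malignancy,183,prefix
malignancy,184,prefix
malignancy,185,prefix
malignancy,186,prefix
malignancy,187,prefix
malignancy,188,prefix
malignancy,189,prefix
malignancy,190,prefix
malignancy,191,prefix
malignancy,192,prefix
malignancy,193,prefix
malignancy,194,prefix
malignancy,195,prefix
malignancy,200,prefix
malignancy,201,prefix
malignancy,202,prefix
malignancy,203,prefix
malignancy,204,prefix
malignancy,205,prefix
malignancy,206,prefix
malignancy,207,prefix
malignancy,208,prefix
severe_liver_disease,5722,prefix
severe_liver_disease,5723,prefix
severe_liver_disease,5724,prefix
severe_liver_disease,5728,prefix
severe_liver_disease,4560,prefix
severe_liver_disease,4561,prefix
severe_liver_disease,4562,prefix
metastatic_tumor,196,prefix
metastatic_tumor,197,prefix
metastatic_tumor,198,prefix
metastatic_tumor,199,exact
metastatic_tumor,1990,prefix
metastatic_tumor,1991,prefix
aids,042,prefix
aids,043,prefix
aids,044,prefix
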