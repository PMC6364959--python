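condition	weight	system	prefix
myocardial_infarction	1	ICD-9	410
myocardial_infarction	1	ICD-10	I21
congestive_heart_failure	1	ICD-9	428
congestive_heart_failure	1	ICD-10	I50
peripheral_vascular_disease	1	ICD-9	440
peripheral_vascular_disease	1	ICD-10	I70
cerebrovascular_disease	1	ICD-9	434
cerebrovascular_disease	1	ICD-10	I63
dementia	1	ICD-9	290
dementia	1	ICD-10	F03
chronic_pulmonary_disease	1	ICD-9	496
chronic_pulmonary_disease	1	ICD-10	J44
rheumatic_disease	1	ICD-9	714
rheumatic_disease	1	ICD-10	M05
peptic_ulcer_disease	1	ICD-9	533
peptic_ulcer_disease	1	ICD-10	K27
mild_liver_disease	1	ICD-9	571.5
mild_liver_disease	1	ICD-10	K74
diabetes_uncomplicated	1	ICD-9	250.0
diabetes_uncomplicated	1	ICD-10	E11.9
diabetes_complicated	2	ICD-9	250.4
diabetes_complicated	2	ICD-10	E11.2
hemiplegia	2	ICD-9	342
hemiplegia	2	ICD-10	G81
renal_disease	2	ICD-9	585
renal_disease	2	ICD-10	N18
malignancy	2	ICD-9	162
malignancy	2	ICD-10	C34
malignancy	2	ICD-9	174
malignancy	2	ICD-10	C50
severe_liver_disease	3	ICD-9	572.2
severe_liver_disease	3	ICD-10	K72.1
metastatic_cancer	6	ICD-9	196
metastatic_cancer	6	ICD-10	C78
aids	6	ICD-9	042
aids	6	ICD-10	B20
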