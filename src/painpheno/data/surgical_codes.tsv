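code	system	surgery_type	description
81.51	ICD-9	orthopedic	total hip replacement
81.54	ICD-9	orthopedic	total knee replacement
0SR90J9	ICD-10	orthopedic	hip joint replacement
38.12	ICD-9	vascular	endarterectomy of head and neck vessels
39.25	ICD-9	vascular	aorta-iliac-femoral bypass
04100J3	ICD-10	vascular	abdominal aortic bypass
47.01	ICD-9	general	laparoscopic appendectomy
51.23	ICD-9	general	laparoscopic cholecystectomy
0DTJ4ZZ	ICD-10	general	appendix resection
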