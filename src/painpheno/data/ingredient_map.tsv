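drug_name	ingredients	therapeutic_class
hydrocodone	hydrocodone	opioid
codeine	codeine	opioid
tramadol	tramadol	opioid
morphine	morphine	opioid
morphine sulfate	morphine	opioid
fentanyl	fentanyl	opioid
hydromorphone	hydromorphone	opioid
oxycodone	oxycodone	opioid
methadone	methadone	opioid
vicodin	hydrocodone;acetaminophen	opioid
lortab	hydrocodone;acetaminophen	opioid
norco	hydrocodone;acetaminophen	opioid
tylenol with codeine	codeine;acetaminophen	opioid
percocet	oxycodone;acetaminophen	opioid
oxycontin	oxycodone	opioid
ms contin	morphine	opioid
dilaudid	hydromorphone	opioid
duragesic	fentanyl	opioid
ultram	tramadol	opioid
acetaminophen	acetaminophen	acetaminophen
sertraline	sertraline	ssri
fluoxetine	fluoxetine	ssri
paroxetine	paroxetine	ssri
citalopram	citalopram	ssri
escitalopram	escitalopram	ssri
fluvoxamine	fluvoxamine	ssri
zoloft	sertraline	ssri
prozac	fluoxetine	ssri
paxil	paroxetine	ssri
celexa	citalopram	ssri
lexapro	escitalopram	ssri
luvox	fluvoxamine	ssri
venlafaxine	venlafaxine	snri
duloxetine	duloxetine	snri
amitriptyline	amitriptyline	tricyclic_antidepressant
nortriptyline	nortriptyline	tricyclic_antidepressant
bupropion	bupropion	other_antidepressant
mirtazapine	mirtazapine	other_antidepressant
lorazepam	lorazepam	benzodiazepine
diazepam	diazepam	benzodiazepine
quetiapine	quetiapine	antipsychotic
lithium	lithium	mood_stabilizer
valproate	valproate	anticonvulsant
ibuprofen	ibuprofen	nsaid
naproxen	naproxen	nsaid
cyclobenzaprine	cyclobenzaprine	muscle_relaxant
gabapentin	gabapentin	gabapentinoid
pregabalin	pregabalin	gabapentinoid
sumatriptan	sumatriptan	triptan
atorvastatin	atorvastatin	statin
simvastatin	simvastatin	statin
metoprolol	metoprolol	beta_blocker
atenolol	atenolol	beta_blocker
lisinopril	lisinopril	ace_inhibitor
losartan	losartan	arb
amlodipine	amlodipine	calcium_channel_blocker
furosemide	furosemide	diuretic
hydrochlorothiazide	hydrochlorothiazide	diuretic
warfarin	warfarin	anticoagulant
clopidogrel	clopidogrel	antiplatelet
aspirin	aspirin	antiplatelet
insulin glargine	insulin glargine	insulin
metformin	metformin	oral_hypoglycemic
levothyroxine	levothyroxine	thyroid
prednisone	prednisone	corticosteroid
omeprazole	omeprazole	ppi
ranitidine	ranitidine	h2_blocker
albuterol	albuterol	bronchodilator
cetirizine	cetirizine	antihistamine
amoxicillin	amoxicillin	antibiotic
ondansetron	ondansetron	antiemetic
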