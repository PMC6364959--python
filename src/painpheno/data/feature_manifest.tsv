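name	component	dtype
age	demographics	continuous
gender_male	demographics	binary
gender_female	demographics	binary
race_white	demographics	binary
race_black	demographics	binary
race_hispanic	demographics	binary
race_asian	demographics	binary
race_other	demographics	binary
marital_married	demographics	binary
marital_single	demographics	binary
insurance_private	demographics	binary
insurance_medicaid	demographics	binary
insurance_medicare	demographics	binary
insurance_other	demographics	binary
bmi	demographics	continuous
charlson_3plus	clinical	binary
opioid_tolerant	clinical	binary
daily_ome	clinical	continuous
preop_pain	clinical	continuous
preop_pain_missing	clinical	binary
systolic_dev	vitals	continuous
diastolic_dev	vitals	continuous
temperature_dev	vitals	continuous
hr_normal	vitals	binary
hr_abnormal	vitals	binary
hr_unknown	vitals	binary
surgery_orthopedic	surgery	binary
surgery_vascular	surgery	binary
surgery_general	surgery	binary
group_ssri_pos_pro_pos	cohort	binary
group_ssri_pos_pro_neg	cohort	binary
group_ssri_neg_pro_pos	cohort	binary
group_ssri_neg_pro_neg	cohort	binary
med_ssri	medications	binary
med_snri	medications	binary
med_tricyclic_antidepressant	medications	binary
med_other_antidepressant	medications	binary
med_benzodiazepine	medications	binary
med_antipsychotic	medications	binary
med_mood_stabilizer	medications	binary
med_anticonvulsant	medications	binary
med_opioid	medications	binary
med_nsaid	medications	binary
med_acetaminophen	medications	binary
med_muscle_relaxant	medications	binary
med_gabapentinoid	medications	binary
med_triptan	medications	binary
med_statin	medications	binary
med_beta_blocker	medications	binary
med_ace_inhibitor	medications	binary
med_arb	medications	binary
med_calcium_channel_blocker	medications	binary
med_diuretic	medications	binary
med_anticoagulant	medications	binary
med_antiplatelet	medications	binary
med_insulin	medications	binary
med_oral_hypoglycemic	medications	binary
med_thyroid	medications	binary
med_corticosteroid	medications	binary
med_ppi	medications	binary
med_h2_blocker	medications	binary
med_bronchodilator	medications	binary
med_antihistamine	medications	binary
med_antibiotic	medications	binary
med_antiemetic	medications	binary
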