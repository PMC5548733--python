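item_key	category	rule_kind	parameters	source_field
asthma	comorbidity	binary	{}	response
copd	comorbidity	binary	{}	response
diabetes_dx	comorbidity	binary	{}	response
dyslipidemia_dx	comorbidity	binary	{}	response
cataract	comorbidity	binary	{}	response
cardiovascular_disease	comorbidity	binary	{}	response
stroke	comorbidity	binary	{}	response
arthritis	comorbidity	binary	{}	response
anemia_dx	comorbidity	binary	{}	response
cancer	comorbidity	binary	{}	response
depression_dx	comorbidity	binary	{}	response
inactivity	functional	binary	{}	response
exercise_capacity	functional	ordinal_map	{"map": {"none": 0, "moderate": 0.5, "severe": 1}}	response
adl_limitation	functional	ordinal_map	{"map": {"none": 0, "moderate": 0.5, "severe": 1}}	response
social_activity_limitation	functional	binary	{}	response
self_care	functional	ordinal_map	{"map": {"none": 0, "moderate": 0.5, "severe": 1}}	response
chewing_difficulty	functional	ordinal_map	{"map": {"none": 0, "moderate": 0.5, "severe": 1}}	response
hearing_impairment	functional	ordinal_map	{"map": {"none": 0, "moderate": 0.5, "severe": 1}}	response
anosmia	functional	binary	{}	response
pain_discomfort	sign_symptom	ordinal_map	{"map": {"none": 0, "moderate": 0.5, "severe": 1}}	response
back_pain	sign_symptom	binary	{}	response
weight_loss	sign_symptom	binary	{}	response
dyspnea	sign_symptom	ordinal_map	{"map": {"none": 0, "moderate": 0.5, "severe": 1}}	response
depression_anxiety	sign_symptom	ordinal_map	{"map": {"none": 0, "moderate": 0.5, "severe": 1}}	response
fatigue	sign_symptom	ordinal_map	{"map": {"none": 0, "moderate": 0.5, "severe": 1}}	response
suicidal_ideation	sign_symptom	binary	{}	response
stress	sign_symptom	ordinal_map	{"map": {"none": 0, "moderate": 0.5, "severe": 1}}	response
sbp	laboratory	threshold_cut	{"bands": [[null, 100, 0.5], [100, 140, 0], [140, 160, 0.5], [160, null, 1]]}	bp.sbp
dbp	laboratory	threshold_cut	{"bands": [[null, 60, 0.5], [60, 90, 0], [90, 100, 0.5], [100, null, 1]]}	bp.dbp
heart_rate_irregular	laboratory	binary	{}	response
pulmonary_function_abnormal	laboratory	binary	{}	response
hemoglobin	laboratory	threshold_cut	{"bands": [[null, 10, 1], [10, 12, 0.5], [12, null, 0]]}	record.hemoglobin
bun	laboratory	threshold_cut	{"bands": [[null, 20, 0], [20, 30, 0.5], [30, null, 1]]}	response
creatinine	laboratory	threshold_cut	{"bands": [[null, 1.2, 0], [1.2, 1.7, 0.5], [1.7, null, 1]]}	record.creatinine
vitamin_d	laboratory	threshold_cut	{"bands": [[null, 10, 1], [10, 20, 0.5], [20, null, 0]]}	response
total_cholesterol	laboratory	threshold_cut	{"bands": [[null, 240, 0], [240, 280, 0.5], [280, null, 1]]}	record.total_cholesterol
triglyceride	laboratory	threshold_cut	{"bands": [[null, 200, 0], [200, 400, 0.5], [400, null, 1]]}	record.triglyceride
hdl_cholesterol	laboratory	threshold_cut	{"bands": [[null, 30, 1], [30, 40, 0.5], [40, null, 0]]}	record.hdl_cholesterol
fasting_glucose	laboratory	threshold_cut	{"bands": [[null, 100, 0], [100, 126, 0.5], [126, null, 1]]}	record.fasting_glucose
urine_protein	laboratory	ordinal_map	{"map": {"negative": 0, "trace": 0.5, "positive": 1}}	response
current_smoking	lifestyle	binary	{}	record.smoker_current
obesity	lifestyle	threshold_cut	{"bands": [[null, 25, 0], [25, null, 1]]}	profile.bmi
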