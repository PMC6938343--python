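study	phenotype	class	polarity
ARIC	2ND AND 3RD SYSTOLIC BP AVERAGE	Systolic Blood Pressure	1
ARIC	AGE 1ST REGULARLY SMOKED CIGARETS	Smoking	1
ARIC	AGE 1ST REGULARLY SMOKED CIGARETS Q29	Smoking	1
ARIC	AGE AT FIRST HEART ATTACK	Myocardial Infarction	1
ARIC	AGE STOPPED SMOKING CIGARETTES	Smoking	1
ARIC	Age at first heart attack	Myocardial Infarction	1
ARIC	BODY MASS INDEX IN KG/(M*M)	Body Mass Index	1
ARIC	Blood Pressure Lowering Medications in the past 2 weeks—Did not	Hypertension	-1
ARIC	Blood Pressure Lowering Medications in the past 2 weeks—Did not take	Hypertension	1
ARIC	Blood Pressure Lowering Medications in the past 2 weeks—Took medication	Hypertension	1
ARIC	C-reactive Protein	C-Reactive Protein Levels	-1
ARIC	CIGARETTE YEARS OF SMOKING	Smoking	1
ARIC	CREATININE (MG-DL)	Creatinine Levels	1
ARIC	Cigarette smoking status—Former smoker	Smoking	1
ARIC	Cigarette smoking status—Never smoker	Smoking	1
ARIC	Coronary Bypass surgery? No	Heart Arterial Surgery	1
ARIC	Coronary Bypass surgery? Yes	Heart Arterial Surgery	1
ARIC	DERIVED GLUCOSE VALUE in mg/dl	Glucose Levels	1
ARIC	Diabetes—lower threshold 126 mg/dL—YES	Diabetes	1
ARIC	Drinker Status—Current drinker	Alcohol Use	1
ARIC	Drinker Status—Current drinker (Y/N)	Alcohol Use	1
ARIC	EVER TAKEN FEMALE HORMONES?	Hormone Use	-1
ARIC	HAVE YOU EVER SMOKED CIGARETTES? (Y/N)	Smoking	1
ARIC	HEART ATTACK EVER DIAGNOSED?	Myocardial Infarction	1
ARIC	HEMATOCRIT	Hematocrit	-1
ARIC	HEMOGLOBIN	Hemoglobin	-1
ARIC	HIGH BP EVER DIAGNOSED?	Hypertension	1
ARIC	HYPERTENSION DEFINITION 5	Hypertension	1
ARIC	HYPERTENSION,DEFINITION 5	Hypertension	-1
ARIC	Heart or arterial surgery? No	Heart Arterial Surgery	-1
ARIC	Heart or arterial surgery? Yes	Heart Arterial Surgery	1
ARIC	INSULIN (UU-ML)	Insulin	1
ARIC	INSULIN in pmol/L	Insulin	1
ARIC	LEFT HEART OR ART SURG—left leg	Heart Arterial Surgery	-1
ARIC	LN+1 2ND AND 3RD SYSTOLIC BP AVERAGE	Systolic Blood Pressure	1
ARIC	LN+1 AGE 1ST REGULARLY SMOKED CIGARETS Q29	Smoking	-1
ARIC	LN+1 AGE 1ST REGULARLY SMOKED CIGARETTES	Smoking	-1
ARIC	LN+1 AGE AT FIRST HEART ATTACK	Myocardial Infarction	-1
ARIC	LN+1 AGE STOPPED SMOKING CIGARETTES	Smoking	-1
ARIC	LN+1 BODY MASS INDEX IN KG/(M*M)	Body Mass Index	1
ARIC	LN+1 C-reactive Protein	C-Reactive Protein Levels	1
ARIC	LN+1 CIGARETTE YEARS OF SMOKING	Smoking	1
ARIC	LN+1 DERIVED GLUCOSE VALUE in mg/dl	Glucose Levels	1
ARIC	LN+1 HEMATOCRIT	Hematocrit	-1
ARIC	LN+1 HEMOGLOBIN	Hemoglobin	-1
ARIC	LN+1 INSULIN (UU-ML)	Insulin	1
ARIC	LN+1 INSULIN in pmol/L	Insulin	1
ARIC	LN+1 RE-CALIBRATED LDL CHOL. in mg/dl	LDL-Cholesterol	1
ARIC	LN+1 STANDING HEIGHT TO NEAREST CM	Height	1
ARIC	LN+1 Smoking duration	Smoking	1
ARIC	LN+1 TOTAL CHOLESTEROL in mmol/L	Total Cholesterol	1
ARIC	LN+1 TOTAL TRIGLYCERIDES in mmol/L	Triglycerides	1
ARIC	LN+1 age at first heart attack	Myocardial Infarction	1
ARIC	LN+1 total cholesterol mg/dL	Total Cholesterol	-1
ARIC	Log (CRP)	C-Reactive Protein Levels	1
ARIC	MI by 2007 (Y/N)	Myocardial Infarction	-1
ARIC	Never used hormones	Hormone Use	-1
ARIC	New Maternal History of Stroke (Y/N)	Stroke	1
ARIC	Number of years abstained from cigarettes	Smoking	-1
ARIC	RE-CALIBRATED HDL CHOL. in mg/dl	HDL-Cholesterol	1
ARIC	RE-CALIBRATED LDL CHOL. in mg/dl	LDL-Cholesterol	1
ARIC	STANDING HEIGHT TO NEAREST CM	Height	1
ARIC	Smoking duration	Smoking	-1
ARIC	TOTAL CHOLESTEROL in mmol/L	Total Cholesterol	-1
ARIC	TOTAL TRIGLYCERIDES in mmol/L	Triglycerides	-1
ARIC	total cholesterol mg/dL	Total Cholesterol	-1
ARIC	triglycerides mg/dL	Triglycerides	-1
MEC	Age started estrogen: reported at baseline	Hormone Use	-1
MEC	Body mass index (BMI) calculated from weight & height at baseline	Body Mass Index	-1
MEC	C-Reactive Protein	C-Reactive Protein Levels	-1
MEC	Currently smoke? (reported at baseline) (Y/N)	Smoking	-1
MEC	Diabetes reported at baseline (Y/N)	Diabetes	-1
MEC	Ethanol Drinks Per Day—2+ drinks	Alcohol Use	1
MEC	Ethanol Drinks Per Day—<1	Alcohol Use	1
MEC	Ethanol Drinks Per Day—<2	Alcohol Use	1
MEC	Ever smoke? (reported at baseline) (Y/N)	Smoking	1
MEC	Heart attack reported at baseline (Y/N)	Myocardial Infarction	-1
MEC	Height (cm)	Height	1
MEC	High blood pressure reported at baseline	Hypertension	1
MEC	LDL cholesterol	LDL-Cholesterol	1
MEC	LN+1 BMI Body mass index (BMI) calculated from weight & height at baseline	Body Mass Index	1
MEC	LN+1 C-Reactive Protein	C-Reactive Protein Levels	1
MEC	LN+1 Height (cm)	Height	-1
MEC	LN+1 Insulin	Insulin	1
MEC	LN+1 Number of years since quit smoking (reported at baseline)	Smoking	-1
MEC	LN+1 Pack-years of smoking (cigarettes) reported at baseline	Smoking	1
MEC	LN+1 SMKQUIT Number of years since quit smoking (reported at baseline)	Smoking	-1
MEC	LN+1 Smoking duration (years) reported at baseline	Smoking	-1
MEC	Number of years since quit smoking (reported at baseline)	Smoking	1
MEC	Pack-years of smoking (cigarettes) reported at baseline	Smoking	1
MEC	Smoking duration (years) reported at baseline	Smoking	1
MEC	Urinary Creatinine	Creatinine Levels	1
WHI	Age at MI	Myocardial Infarction	1
WHI	Age first told had diabetes	Diabetes	1
WHI	Age quit smoking	Smoking	1
WHI	Age started treatment for diabetes	Diabetes	-1
WHI	Age stroke	Stroke	1
WHI	Age told of hypertension	Hypertension	1
WHI	Body mass index (BMI) calculated from weight & height at baseline	Body Mass Index	1
WHI	CRP	C-Reactive Protein Levels	-1
WHI	Coronary bypass surgery ever (Y/N)	Heart Arterial Surgery	1
WHI	Diabetes ever	Diabetes	1
WHI	Hematocrit	Hematocrit	-1
WHI	Hemoglobin	Hemoglobin	-1
WHI	Hypertension ever (Y/N)	Hypertension	1
WHI	Insulin	Insulin	1
WHI	LN+1 Age at MI	Myocardial Infarction	1
WHI	LN+1 Age quit smoking	Smoking	-1
WHI	LN+1 Age stroke	Stroke	1
WHI	LN+1 Age told of hypertension	Hypertension	-1
WHI	LN+1 Body mass index (BMI) calculated from weight & height at baseline	Body Mass Index	-1
WHI	LN+1 CRP	C-Reactive Protein Levels	-1
WHI	LN+1 Coronary bypass surgery ever (Y/N)	Heart Arterial Surgery	1
WHI	LN+1 F2 age at MI	Myocardial Infarction	-1
WHI	LN+1 F33 Age started treatment for diabetes	Diabetes	1
WHI	LN+1 Hematocrit	Hematocrit	-1
WHI	LN+1 Hemoglobin	Hemoglobin	-1
WHI	LN+1 Pack years of smoking	Smoking	-1
WHI	LN+1 alcohol intake	Alcohol Use	-1
WHI	LN+1 glucose	Glucose Levels	1
WHI	LN+1 normalized LDL	LDL-Cholesterol	1
WHI	LN+1 normalized natural log transformed triglycerides	Triglycerides	1
WHI	LN+1 systolic blood pressure	Systolic Blood Pressure	1
WHI	LN+1 years a regular smoker	Smoking	-1
WHI	MI	Myocardial Infarction	-1
WHI	MI ever (Y/N)	Myocardial Infarction	-1
WHI	Natural Log normalized LDL	LDL-Cholesterol	-1
WHI	Never hypertensive (Y/N)	Hypertension	-1
WHI	Normalized LDL	LDL-Cholesterol	1
WHI	Pack years of smoking	Smoking	1
WHI	Percutaneous transluminal coronary angioplasty (Y/N)	Heart Arterial Surgery	-1
WHI	Smoking—Former	Smoking	-1
WHI	Smoking—Former (Y/N)	Smoking	1
WHI	Smoking—Never	Smoking	1
WHI	Smoking—Never (Y/N)	Smoking	1
WHI	Smoking—current (Y/N)	Smoking	1
WHI	Treated hypertensive	Hypertension	-1
WHI	Treated hypertensive (Y/N)	Hypertension	1
WHI	Years a regular smoker	Smoking	1
WHI	age at MI	Myocardial Infarction	-1
WHI	alcohol intake	Alcohol Use	1
WHI	glucose	Glucose Levels	-1
WHI	insulin	Insulin	1
WHI	normalized HDL	HDL-Cholesterol	1
WHI	normalized LDL	LDL-Cholesterol	1
WHI	normalized natural log transformed triglycerides	Triglycerides	1
WHI	pack years of smoking	Smoking	1
WHI	systolic blood pressure	Systolic Blood Pressure	1
WHI	total cholesterol	Total Cholesterol	1
WHI	treated diabetes	Diabetes	1
WHI	years a regular smoker	Smoking	1
ARIC	WHITE BLOOD COUNT	White Blood Count	1
WHI	White blood count	White Blood Count	1
ARIC	FIBRINOGEN in mg/dl	Fibrinogen	1
WHI	Platelet count	Platelet	1
ARIC	2ND AND 3RD DIASTOLIC BP AVERAGE	Diastolic Blood Pressure	1
WHI	diastolic blood pressure	Diastolic Blood Pressure	1
WHI	Age at menarche	Menarche	1
ARIC	HEART RATE	Heart Rate	1
WHI	Heart failure ever (Y/N)	Heart Failure	1
ARIC	WEIGHT IN KG	Weight	1
WHI	Episodes of vigorous activity per week	Activity Levels, Personal	1
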