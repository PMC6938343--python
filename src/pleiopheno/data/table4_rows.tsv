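variant_id	chrom	pos	classes	opposite_direction	coded_allele	caf
rs10889334	1	62491528	Smoking|LDL-Cholesterol		C	0.34
rs61771778	1	72461172	C-Reactive Protein Levels|Myocardial Infarction		G	0.043
rs2994429	1	84709901	Hemoglobin|Hematocrit		A	0.32
rs10798572	1	177821975	Hypertension|Smoking		G	0.27
rs943763	1	177867129	LDL-Cholesterol|Smoking		C	0.46
rs1052238	1	198665496	C-Reactive Protein Levels|Diabetes		G	0.45
rs568938	2	21080744	LDL-Cholesterol|Smoking		A	0.42
rs6722366	2	27809087	Insulin|Height	*	C	0.027
rs56197751	2	27835291	Insulin|Height	*	A	0.028
rs114117339	2	27855059	Insulin|Height	*	A	0.027
rs6760908	2	27855874	Insulin|Height	*	A	0.027
rs12622858	2	50130369	Hemoglobin|Hematocrit		A	0.21
rs17033788	2	67566015	Hormone Use|Hypertension		C	0.059
rs13186242	5	136857921	Smoking|Hypertension	*	A	0.28
rs4958487	5	151684113	Glucose Levels|Hypertension		A	0.4
rs9349379	6	12903725	Smoking|Diabetes|Hypertension	*	G	0.099
rs79239785	6	20602709	Alcohol Use|Hypertension		A	0.02
rs1728312	7	23231308	Smoking|Alcohol Use		G	0.05
rs2390859	7	23995928	Smoking|Heart Arterial Surgery		A	0.17
rs4722315	7	24006654	Smoking|Heart Arterial Surgery		G	0.17
rs2106922	7	27969614	Hemoglobin|Hematocrit		A	0.22
rs114374279	7	44532122	Alcohol Use|Smoking		G	0.02
rs11983880	7	73708374	Glucose Levels|Diabetes		A	0.1
rs10974448	9	4308010	Hematocrit|Hemoglobin		A	0.2
rs2756916	9	101915669	Body Mass Index|C-Reactive Protein Levels		C	0.026
rs7923036	10	1433616	Myocardial Infarction|Smoking		G	0.19
rs787037	10	26504353	Smoking|HDL-Cholesterol		G	0.21
rs17875327	10	92515052	Insulin|Triglycerides		G	0.018
rs942008	10	96397655	Hypertension|Systolic Blood Pressure		G	0.18
rs76394293	11	17372388	Insulin|Glucose Levels		A	0.032
rs1939120	11	64537243	Smoking|Hematocrit		A	0.37
rs17376366	12	20339790	Stroke|Creatinine Levels		G	0.076
rs115487129	12	89395852	Smoking|Alcohol Use		C	0.052
rs7139221	12	110853890	Insulin|Smoking	*	A	0.14
rs61944267	12	110856526	Insulin|Smoking	*	G	0.14
rs113945414	12	110859018	Insulin|Smoking	*	A	0.15
rs10774711	12	113697994	Systolic Blood Pressure|Myocardial Infarction		A	0.49
rs60136502	15	90965307	Insulin|Total Cholesterol		C	0.11
rs11865790	16	47399623	Alcohol Use|C-Reactive Protein Levels		G	0.35
rs8058543	16	53096347	Heart Arterial Surgery|Myocardial Infarction		A	0.044
rs2926143	16	64224173	Hypertension|Smoking	*	G	0.49
rs4260044	16	85238638	Body Mass Index|C-Reactive Protein Levels		A	0.48
rs4334353	17	55374378	Smoking|Myocardial Infarction	*	A	0.32
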