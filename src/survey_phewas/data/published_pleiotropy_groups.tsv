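snp	class_label	stratum	direction
rs12678919	HDL Cholesterol	NHW	+
rs12678919	Triglycerides	NHW	+
rs562338	Cholesterol	NHW	-
rs562338	Hearing	NHB	+
rs174547	Ferritin	MA	+
rs174547	Folate	NHB	-
rs174547	Triglycerides	NHW	-
rs2338104	Hearing	NHW	+
rs2338104	Hemoglobin	NHW	-
rs780094	Glucose	MA	+
rs780094	Potassium intake	MA	-
rs780094	Vitamin B6 intake	MA	-
rs6855911	Kidney (Uric Acid)	MA	-
rs6855911	Kidney (Uric Acid)	NHB	-
rs6855911	Body Measurements (Leg)	NHB	+
rs646776	Cholesterol	MA	-
rs646776	Cholesterol	NHB	-
rs646776	Cholesterol	NHW	-
rs646776	LDL Cholesterol	MA	-
rs964184	Cholesterol	MA	+
rs964184	Cholesterol	NHW	+
rs964184	Triglycerides	MA	+
rs964184	Triglycerides	NHW	+
rs964184	Vitamin E	MA	+
rs964184	Vitamin E	NHW	+
rs1800588	Cholesterol	NHW	+
rs1800588	Folate	MA	-
rs1800588	Triglycerides	NHW	+
rs1800588	Vitamin E	NHW	+
rs2231142	Blood Pressure (Diastolic)	MA	+
rs2231142	Kidney (Uric Acid)	MA	-
rs2231142	Kidney (Uric Acid)	NHW	-
rs2231142	Protoporphyrin	MA	-
rs2231142	Protoporphyrin	NHW	-
rs328	HDL Cholesterol	MA	+
rs328	HDL Cholesterol	NHW	+
rs328	Triglycerides	NHW	-
rs12740374	Cholesterol	MA	-
rs12740374	Cholesterol	NHB	-
rs12740374	Cholesterol	NHW	-
rs12740374	LDL Cholesterol	MA	-
rs12740374	LDL Cholesterol	NHB	-
rs28927680	Triglycerides	MA	-
rs28927680	Triglycerides	NHW	-
rs28927680	Vitamin E	NHW	-
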