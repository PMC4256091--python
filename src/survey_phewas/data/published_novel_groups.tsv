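snp	class_label	stratum	direction
rs11206510	Globulin	MA	+
rs1260326	Vitamin A	NHW	+
rs13266634	Vitamin E	NHW	-
rs174547	Ferritin	MA	+
rs174547	Folate	NHB	-
rs1800588	Folate	MA	-
rs1800588	Vitamin E	NHW	+
rs2231142	Blood Pressure (Diastolic)	MA	+
rs2231142	Protoporphyrin	MA	-
rs2231142	Protoporphyrin	NHW	-
rs2338104	Hearing	NHW	+
rs2338104	Hemoglobin	NHW	-
rs28927680	Vitamin E	NHW	-
rs4355801	White Blood Cell	NHB	+
rs6855911	Body Measurements (Leg)	NHB	+
rs562338	Hearing	NHB	+
rs780094	Potassium intake	MA	-
rs780094	Vitamin B6 intake	MA	-
rs1800795	White Blood Cell	NHB	-
rs2237895	Body Measurement (Arm)	MA	-
rs1529729	Broken/Fractured Bone	NHW	+
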