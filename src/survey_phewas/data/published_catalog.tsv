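snp	prior_class	related_group	direction	source
rs11206510	LDL Cholesterol	lipids		20864672
rs1260326	Triglycerides	lipids		18454146
rs1260326	Cholesterol	lipids		20657596
rs13266634	Diabetes			17460697
rs174547	HDL Cholesterol	lipids		20639392
rs174547	Triglycerides	lipids		19060906
rs1800588	HDL Cholesterol	lipids		18193044
rs2231142	Kidney (Uric Acid)			22229870
rs2338104	HDL Cholesterol	lipids		19060906
rs28927680	Triglycerides	lipids		18193044
rs28927680	HDL Cholesterol	lipids		18193044
rs4355801	Bone density			18455228
rs6855911	Kidney (Uric Acid)			17997608
rs562338	LDL Cholesterol	lipids		18714375
rs780094	Triglycerides	lipids		18439548
rs780094	LDL Cholesterol	lipids		22399527
rs780094	Glucose			18193044
rs1800795	Inflammation (C-reactive protein)			15820616
rs2237895	Diabetes			20174558
rs1529729	LDL Cholesterol	lipids		18714375
rs12678919	HDL Cholesterol	lipids		18193044
rs12678919	Triglycerides	lipids		18193044
rs964184	Cholesterol	lipids		21943158
rs964184	LDL Cholesterol	lipids		21943158
rs964184	Triglycerides	lipids		21943158
rs964184	HDL Cholesterol	lipids		21943158
rs964184	Vitamin E			21943158
rs646776	Cholesterol	lipids		19060906
rs646776	LDL Cholesterol	lipids		19198609
rs328	HDL Cholesterol	lipids		18193044
rs328	Triglycerides	lipids		18193044
rs12740374	LDL Cholesterol	lipids		19060906
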