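related_group	class_label
lipids	Cholesterol
lipids	HDL Cholesterol
lipids	LDL Cholesterol
lipids	Triglycerides
lipids	Lipoprotein
lipids	Apolipoprotein
lipids	High Cholesterol
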