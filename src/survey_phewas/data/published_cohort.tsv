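survey	n	pct_female	pct_nhw	pct_nhb	pct_ma
NHANES III	7159	56.67	36.74	29.45	28.96
Continuous NHANES	7839	51.79	51.07	17.22	23.94
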