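exposure	mediator	outcome	c	se_c	b	se_b	a	se_a
BMI	Leptin	Pre-eclampsia	0.737	0.135	0.887	0.232	0.417	0.0262
BMI	Fasting insulin	Pre-eclampsia	0.737	0.135	1.42	0.441	0.144	0.0141
BMI	Insulin sensitivity	Pre-eclampsia	0.737	0.135	-0.503	0.169	-0.281	0.0490
WHR	Fasting insulin	Pre-eclampsia	0.449	0.151	1.27	0.473	0.129	0.0159
WHR	Insulin sensitivity	Pre-eclampsia	0.449	0.151	-0.793	0.183	-0.283	0.0601
WHR	Insulin sensitivity	Uterine fibroids	0.218	0.0637	-0.202	0.083	-0.283	0.0601
WHRadjBMI	Insulin sensitivity	Pre-eclampsia	0.358	0.118	-0.519	0.205	-0.168	0.0427
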