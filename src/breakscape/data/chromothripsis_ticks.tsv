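tumor	bpi	subtype	chr6	chr7	chr8	chr9	chr11	chr17	chr19	chr21
T61	30	ER+	0	1	0	0	1	0	0	0
T23	69	ER+	1	0	0	0	0	0	0	0
T46	139	ER+	0	0	1	0	0	0	1	0
T147	434	ER+	0	0	0	0	1	0	0	0
T190	35	TNBC	0	0	0	1	0	0	0	0
T199	93	TNBC	0	0	1	0	0	0	0	0
T79	104	TNBC	0	1	0	0	0	0	0	0
T333	64	HER2+	1	0	1	0	0	1	0	0
T111	141	HER2+	0	0	1	0	0	1	0	0
T207	162	HER2+	0	0	0	0	0	1	0	0
T74	215	HER2+	0	0	1	0	0	1	0	1
T64	329	HER2+	0	0	0	0	0	1	0	1
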