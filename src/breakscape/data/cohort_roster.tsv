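sample	subtype	ploidy	bpi	chromothripsis
T39	ER+	D/T	25	0
T61	ER+	D/T	30	1
T27	ER+	D/T	59	0
T23	ER+	A	69	1
T55	ER+	A	91	0
T26	ER+	A	121	0
T46	ER+	A	139	1
T147	ER+	D/T	434	1
T333	HER2+	A	64	1
T260	HER2+	A	82	0
T70	HER2+	A	136	0
T111	HER2+	A	141	1
T207	HER2+	A	162	1
T155	HER2+	A	187	0
T74	HER2+	A	215	1
T64	HER2+	A	329	1
T214	HER2+	A	557	0
T190	TNBC	T	35	1
T253	TNBC	T	74	0
T117	TNBC	A	91	0
T199	TNBC	A	93	1
T79	TNBC	A	104	1
T57	TNBC	A	105	0
T221	TNBC	D	122	0
T25	TNBC	A	150	0
T76	TNBC	D	152	0
T52	TNBC	A	264	0
T210	TNBC	A	309	0
T222	TNBC	A	714	0
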