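individual_id	country	site_label	completeness	sex	age	culture	radiocarbon	reported_score
032	RO	Blejoi (Prahova District, Romania) 2016, mound III, grave 3	95	m	25-35	Pre-Yamnaya	(DeA-8814) 4437 +/- 34 B.P., 3331-2927 calBCE	7
034	RO	Blejoi (Prahova District, Romania), mound III, grave 5	100	m	25-35	Pre-Yamnaya	(DeA-8815) 4452 +/- 33 B.P., 3338-2939 calBCE	5
064	RO	Strejnicu (Prahova District, Romania) 2011, mound I, grave 3	95	m	30-40	Yamnaya	(Hd-30719) 4106 +/- 38 B.P., 2869-2501 calBCE; (BRAMS-3586) 4190 +/- 28 B.P., 2891-2669 calBCE	12
081	BG	Boyanovo (Yambol District, Bulgaria), "Bajlar Kajrak," mound I, grave 13	85	m	22-26	Yamnaya		5
082	BG	Boyanovo (Yambol District, Bulgaria), "Bajlar Kajrak," mound III, grave 2	90	m	35-45	Post-Yamnaya		5
092	BG	Boyanovo (Yambol District, Bulgaria), "Bajlar Kajrak," mound I, grave 17	90	m	25-30	Pre-Yamnaya (early Yamnaya?)		3
103	CZ	Vlineves (Melnik District, Czech Republic), grave 4214A; inv. no.: P7A 41603	95	m	25-35	Corded Ware	(CRL-9194) 4133 +/- 87 B.P., 2896-2488 calBCE; (MAMS-44711) 4174 +/- 25 B.P., 2881-2669 calBCE	5
116	BG	Malomirovo (Yambol District, Bulgaria) 2021, grave 17	90	m	65-75	Yamnaya	(Poz-141946) 4315 +/- 35 B.P., 3018-2884 calBCE	7
118	BG	Vetrino (Varna District, Bulgaria) 2020, Necropole 1, mound XXXIV, grave 3	95	m	25-35	Yamnaya	(SUERC-95535) 4138 +/- 22 B.P., 2873-2623 calBCE	10
130	BG	Vetrino (Varna District, Bulgaria), Necropole 3, mound I, grave 9	80	(f)	35-45	Yamnaya	(SUERC-97452) 4172 +/- 27 B.P., 2883-2635 calBCE	6
135	BG	Chudomir (Razgrad District, Bulgaria), mound I, grave 9	85	m	35-50	Yamnaya		4
148	RO	Medgidia (Constanta District, Romania), mound V/VI, grave 1a	100	m	35-40	Post-Yamnaya		3
153	RO	Medgidia (Constanta District, Romania) 2010, mound VI, grave 6	100	m	40-50	Middle Bronze Age	(DeA-9728) 3254 +/- 28 B.P., 1611-1446 calBCE	9
161	RO	Medgidia (Constanta District, Romania) 2010, mound V, grave 4	85	m	45-60	Middle Bronze Age	(DeA-9667) 3361 +/- 32 B.P., 1750-1540 calBCE	7
164	RO	Medgidia (Constanta District, Romania), mound V, grave 7	95	(m)	15-18	Yamnaya		4
166	RO	Medgidia (Constanta District, Romania), mound III, grave 1-2, individual 1	70	m	35-45	Pre-Yamnaya		6
170	RO	Medgidia (Constanta District, Romania), mound III, grave 11	65	(m)	25-35	Yamnaya	(BRAMS-3579) 4129 +/- 28 B.P., 2870-2581 calBCE	7
174	RO	Medgidia (Constanta District, Romania), mound III, grave 16	75	(f)	17-20	Yamnaya	(BRAMS-3582) 4106 +/- 28 B.P., 2865-2505 calBCE	6
177	RO	Aliman (Constanta District, Romania), grave 1/s	75	m	40-50	Yamnaya	(BRAMS-3575) 4096 +/- 28 B.P., 2859-2500 calBCE	6
186	HU	Debrecen (Hajdu-Bihar District, Hungary), Basahalom 1906/1326/32	30	(m)	20-40	Yamnaya	(DeA-34604) 4322 +/- 32 B.P., 3018-2888 calBCE	7
198	HU	Kunhegyes (Jasz-Nagykun-Szolnok District, Hungary), Nagyallas-halom grave 18	75	m	35-50	Yamnaya	(Poz-39456) 4195 +/- 35 B.P., 2895-2636 calBCE	3
209	HU	Csongrad (Csongrad-Csanad District, Hungary) 1963, Bardos-farmstead, -Kettoshalom, grave 1	100	m	25-35	Copper Age	(Poz-41865) 5470 +/- 40 B.P., 4442-4243 calBCE	9
213	HU	Devavanya (Bekes District, Hungary) 1969, Barce-halom, grave 1	90	m	40-50	Yamnaya	(DeA-8221) 4279 +/- 22 B.P., 2916-2881 calBCE	10
215	HU	Balmazujvaros (Hajdu-Bihar District, Hungary) 1964, Arkusmajor, -Kettoshalom, grave 1	40	m	35-45	Yamnaya	(Poz-39461) 4320 +/- 35 B.P., 3021-2886 calBCE	7
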