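mol_id	name	ob	dl	herb
MOL000449	Stigmasterol	43.83	0.76	Gusuibu
MOL000492	(+)-catechin	54.83	0.24	Gusuibu
MOL000569	digallate	61.85	0.26	Gusuibu
MOL001040	(2R)-5,7-dihydroxy-2-(4-hydroxyphenyl)chroman-4-one	42.36	0.21	Gusuibu
MOL001978	Aureusidin	53.42	0.24	Gusuibu
MOL002914	Eriodyctiol (flavanone)	41.35	0.24	Gusuibu
MOL004328	naringenin	59.29	0.21	Gusuibu
MOL005190	eriodictyol	71.79	0.24	Gusuibu
MOL009061	22-Stigmasten-3-one	39.25	0.76	Gusuibu
MOL009063	Cyclolaudenol acetate	41.66	0.79	Gusuibu
MOL009075	cycloartenone	40.57	0.79	Gusuibu
MOL009076	cyclolaudenol	39.05	0.79	Gusuibu
MOL009078	davallioside A_qt	62.65	0.51	Gusuibu
MOL009087	marioside_qt	70.79	0.19	Gusuibu
MOL009091	xanthogalenol	41.08	0.32	Gusuibu
MOL000006	luteolin	36.16	0.25	Gusuibu
MOL000358	beta-sitosterol	36.91	0.75	Gusuibu
MOL000422	kaempferol	41.88	0.24	Gusuibu
MOL005320	arachidonate	45.57	0.2	Roucongrong
MOL005384	suchilactone	57.52	0.56	Roucongrong
MOL008871	Marckine	37.05	0.69	Roucongrong
MOL007563	Yangambin	57.53	0.81	Roucongrong
MOL000098	quercetin	46.43	0.28	Roucongrong
MOL000358	beta-sitosterol	36.91	0.75	Roucongrong
MOL000622	Magnograndiolide	63.71	0.19	Yinyanghuo
MOL004367	olivil	62.23	0.41	Yinyanghuo
MOL004388	CID 12115137	60.64	0.66	Yinyanghuo
MOL004382	Yinyanghuo A	56.96	0.77	Yinyanghuo
MOL004396	CID 12468616	52.31	0.22	Yinyanghuo
MOL004386	Yinyanghuo E	51.63	0.55	Yinyanghuo
MOL004391	8-prenyl-flavone	48.54	0.25	Yinyanghuo
MOL004384	Yinyanghuo C	45.67	0.5	Yinyanghuo
MOL004373	Anhydroicaritin	45.41	0.44	Yinyanghuo
MOL001645	Linoleyl acetate	42.1	0.2	Yinyanghuo
MOL004394	Anhydroicaritin-3-O-alpha-l-rhamnoside	41.58	0.61	Yinyanghuo
MOL004425	Icariin	41.58	0.61	Yinyanghuo
MOL004380	2,7-Dihydrohomoerysotrine	39.14	0.49	Yinyanghuo
MOL003542	8-Isopentenyl-kaempferol	38.04	0.39	Yinyanghuo
MOL001510	24-epicampesterol	37.58	0.71	Yinyanghuo
MOL001771	poriferast-5-en-3beta-ol	36.91	0.75	Yinyanghuo
MOL000359	sitosterol	36.91	0.75	Yinyanghuo
MOL003044	Chryseriol	35.85	0.27	Yinyanghuo
MOL001792	Liquiritigenin	32.76	0.18	Yinyanghuo
MOL004427	Icariside A7	31.91	0.86	Yinyanghuo
MOL000006	luteolin	36.16	0.25	Yinyanghuo
MOL000098	quercetin	46.43	0.28	Yinyanghuo
MOL000422	kaempferol	41.88	0.24	Yinyanghuo
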