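mol_id	name	herb	score	is_control	missing
THC	THC	control	52.8724	1	0
MOL004373	Anhydroicaritin	Yinyanghuo	50.993	0	0
MOL003542	8-Isopentenyl-kaempferol	Yinyanghuo	50.861	0	0
MOL009078	davallioside A_qt	Gusuibu	50.432	0	0
MOL009091	xanthogalenol	Gusuibu	49.413	0	0
MOL001645	Linoleyl acetate	Yinyanghuo	49.054	0	0
MOL004367	olivil	Yinyanghuo	47.226	0	0
MOL004380	2,7-Dihydrohomoerysotrine	Yinyanghuo	44.539	0	0
MOL000098	quercetin	Roucongrong;Yinyanghuo	43.411	0	0
MOL001040	(2R)-5,7-dihydroxy-2-(4-hydroxyphenyl)chroman-4-one	Gusuibu	42.865	0	0
MOL004396	CID 12468616	Yinyanghuo	42.624	0	0
MOL000422	kaempferol	Gusuibu;Yinyanghuo	42.237	0	0
MOL000569	digallate	Gusuibu	41.823	0	0
MOL003044	Chryseriol	Yinyanghuo	41.674	0	0
MOL005190	eriodictyol	Gusuibu	41.543	0	0
MOL002914	Eriodyctiol (flavanone)	Gusuibu	41.484	0	0
MOL009087	marioside_qt	Gusuibu	41.415	0	0
MOL000006	luteolin	Gusuibu;Yinyanghuo	41.160	0	0
MOL001978	Aureusidin	Gusuibu	40.544	0	0
MOL004382	Yinyanghuo A	Yinyanghuo	40.506	0	0
MOL005320	arachidonate	Roucongrong	40.259	0	0
MOL007563	Yangambin	Roucongrong	39.614	0	0
MOL005384	suchilactone	Roucongrong	39.439	0	0
MOL000492	(+)-catechin	Gusuibu	38.231	0	0
MOL004328	naringenin	Gusuibu	36.992	0	0
MOL001792	Liquiritigenin	Yinyanghuo	36.862	0	0
MOL004427	Icariside A7	Yinyanghuo	36.796	0	0
MOL000622	Magnograndiolide	Yinyanghuo	36.103	0	0
MOL004388	CID 12115137	Yinyanghuo	34.448	0	0
MOL004391	8-prenyl-flavone	Yinyanghuo	34.278	0	0
MOL004386	Yinyanghuo E	Yinyanghuo	28.124	0	0
MOL004384	Yinyanghuo C	Yinyanghuo	26.056	0	0
MOL008871	Marckine	Roucongrong	24.876	0	0
MOL001510	24-epicampesterol	Yinyanghuo	18.730	0	0
MOL009061	22-Stigmasten-3-one	Gusuibu	17.976	0	0
MOL009076	cyclolaudenol	Gusuibu	16.461	0	0
MOL009075	cycloartenone	Gusuibu	15.128	0	0
MOL009063	Cyclolaudenol acetate	Gusuibu	5.975	0	0
MOL000358	beta-sitosterol	Gusuibu;Roucongrong	-1.136	0	0
MOL000359	sitosterol	Yinyanghuo	-9.681	0	0
MOL001771	poriferast-5-en-3beta-ol	Yinyanghuo	-17.121	0	0
MOL000449	Stigmasterol	Gusuibu	-21.647	0	0
MOL004394	Anhydroicaritin-3-O-alpha-l-rhamnoside	Yinyanghuo		0	1
MOL004425	Icariin	Yinyanghuo		0	1
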