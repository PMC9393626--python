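mol_id	name	herb	score	is_control	missing
GQD	GQD	control	65.414	1	0
MOL008871	Marckine	Roucongrong	54.530	0	0
MOL009091	Xanthogalenol	Gusuibu	53.776	0	0
MOL005320	Arachidonate	Roucongrong	51.688	0	0
MOL004382	Yinyanghuo A	Yinyanghuo	51.053	0	0
MOL001645	Linoleyl acetate	Yinyanghuo	50.828	0	0
MOL005384	Suchilactone	Roucongrong	50.592	0	0
MOL009078	davallioside A_qt	Gusuibu	49.776	0	0
MOL004367	Olivil	Yinyanghuo	47.811	0	0
MOL007563	Yangambin	Roucongrong	47.178	0	0
MOL004396	CID 12468616	Yinyanghuo	46.845	0	0
MOL003542	8-Isopentenyl-kaempferol	Yinyanghuo	46.101	0	0
MOL000569	Digallate	Gusuibu	45.932	0	0
MOL005190	Eriodictyol	Gusuibu	44.156	0	0
MOL000492	(+)-catechin	Gusuibu	43.466	0	0
MOL004373	Anhydroicaritin	Yinyanghuo	43.293	0	0
MOL001978	Aureusidin	Gusuibu	43.188	0	0
MOL004384	Yinyanghuo C	Yinyanghuo	42.640	0	0
MOL000098	Quercetin	Roucongrong;Yinyanghuo	42.464	0	0
MOL001040	(2R)-5,7-dihydroxy-2-(4-hydroxyphenyl)chroman-4-one	Gusuibu	42.130	0	0
MOL004386	Yinyanghuo E	Yinyanghuo	41.695	0	0
MOL004391	8-prenyl-flavone	Yinyanghuo	40.476	0	0
MOL003044	Chryseriol	Yinyanghuo	39.899	0	0
MOL002914	Eriodyctiol (flavanone)	Gusuibu	39.767	0	0
MOL001792	Liquiritigenin	Yinyanghuo	39.745	0	0
MOL009087	marioside_qt	Gusuibu	39.734	0	0
MOL000006	Luteolin	Gusuibu;Yinyanghuo	39.021	0	0
MOL004380	2,7-Dihydrohomoerysotrine	Yinyanghuo	38.627	0	0
MOL004328	Naringenin	Gusuibu	38.601	0	0
MOL000422	Kaempferol	Gusuibu;Yinyanghuo	38.113	0	0
MOL004427	Icariside A7	Yinyanghuo	36.341	0	0
MOL000622	Magnograndiolide	Yinyanghuo	33.682	0	0
MOL009061	22-Stigmasten-3-one	Gusuibu	30.159	0	0
MOL004388	CID 12115137	Yinyanghuo	25.106	0	0
MOL001771	poriferast-5-en-3beta-ol	Yinyanghuo	17.943	0	0
MOL009075	cycloartenone	Gusuibu	16.345	0	0
MOL001510	24-epicampesterol	Yinyanghuo	15.266	0	0
MOL000449	Stigmasterol	Gusuibu	11.704	0	0
MOL000359	sitosterol	Yinyanghuo	8.864	0	0
MOL009076	cyclolaudenol	Gusuibu	-0.891	0	0
MOL000358	beta-sitosterol	Gusuibu;Roucongrong	-8.363	0	0
MOL004394	Anhydroicaritin-3-O-alpha-l-rhamnoside	Yinyanghuo		0	1
MOL004425	Icariin	Yinyanghuo		0	1
MOL009063	Cyclolaudenol acetate	Gusuibu		0	1
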