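mol_id	name	ob	dl	herb
MOL002235	Eupation	50.8	0.41	Dahuang
MOL002251	Mutatochrome	48.64	0.61	Dahuang
MOL002259	Physciondiglucoside	41.65	0.63	Dahuang
MOL002260	Procyanidin B-5,3'-O-gallate	31.99	0.32	Dahuang
MOL002268	Rhein	47.07	0.28	Dahuang
MOL002276	Sennoside E_qt	50.69	0.61	Dahuang
MOL002280	Torachrysone-8-O-beta-D-(6'-oxayl)-glucoside	43.02	0.74	Dahuang
MOL002281	Toralactone	46.46	0.24	Dahuang
MOL002288	Emodin-1-O-beta-D-glucopyranoside	44.81	0.8	Dahuang
MOL002293	Sennoside D_qt	61.06	0.61	Dahuang
MOL002297	Daucosterol_qt	35.89	0.7	Dahuang
MOL002303	Palmidin A	32.45	0.65	Dahuang
MOL000358	Beta-sitosterol	36.91	0.75	Dahuang
MOL000471	Aloe-emodin	83.38	0.24	Dahuang
MOL000554	Gallic acid-3-O-(6'-O-galloyl)-glucoside	30.25	0.67	Dahuang
MOL000096	(-)-Catechin	49.68	0.24	Dahuang
MOL001454	Berberine	36.86	0.78	Huanglian
MOL013352	Obacunone	43.29	0.77	Huanglian
MOL002894	Berberrubine	35.74	0.73	Huanglian
MOL002897	Epiberberine	43.09	0.78	Huanglian
MOL002903	(R)-canadine	55.37	0.77	Huanglian
MOL002904	Berlambine	36.68	0.82	Huanglian
MOL002907	Corchoroside A_qt	104.95	0.78	Huanglian
MOL000622	Magnograndiolide	63.71	0.19	Huanglian
MOL000762	Palmidin A	35.36	0.65	Huanglian
MOL000785	Palmatine	64.6	0.65	Huanglian
MOL000098	Quercetin	46.43	0.28	Huanglian
MOL001458	Coptisine	30.67	0.86	Huanglian
MOL002668	Worenine	45.83	0.87	Huanglian
MOL008647	Moupinamide	86.71	0.26	Huanglian
MOL001689	Acacetin	34.97	0.24	Huangqin
MOL000173	Wogonin	30.68	0.23	Huangqin
MOL000228	(2R)-7-Hydroxy-5-methoxy-2-phenylchroman-4-one	55.23	0.2	Huangqin
MOL002714	Baicalein	33.52	0.21	Huangqin
MOL002908	5,8,2'-Trihydroxy-7-methoxyflavone	37.01	0.27	Huangqin
MOL002909	5,7,2,5-Tetrahydroxy-8,6-dimethoxyflavone	33.82	0.45	Huangqin
MOL002910	Carthamidin	41.15	0.24	Huangqin
MOL002911	2,6,2',4'-Tetrahydroxy-6'-methoxychaleone	69.04	0.22	Huangqin
MOL002913	Dihydrobaicalin_qt	40.04	0.21	Huangqin
MOL002914	Eriodyctiol (flavanone)	41.35	0.24	Huangqin
MOL002915	Salvigenin	49.07	0.33	Huangqin
MOL002917	5,2',6'-Trihydroxy-7,8-dimethoxyflavone	45.05	0.33	Huangqin
MOL002925	5,7,2',6'-Tetrahydroxyflavone	37.01	0.24	Huangqin
MOL002926	Dihydrooroxylin A	38.72	0.23	Huangqin
MOL002927	Skullcapflavone II	69.51	0.44	Huangqin
MOL002928	Oroxylin a	41.37	0.23	Huangqin
MOL002932	Panicolin	76.26	0.29	Huangqin
MOL002933	5,7,4'-Trihydroxy-8-methoxyflavone	36.56	0.27	Huangqin
MOL002934	Neobaicalein	104.34	0.44	Huangqin
MOL002937	Dihydrooroxylin	66.06	0.23	Huangqin
MOL000358	Beta-sitosterol	36.91	0.75	Huangqin
MOL000359	Sitosterol	36.91	0.75	Huangqin
MOL000525	Norwogonin	39.4	0.21	Huangqin
MOL000552	5,2'-Dihydroxy-6,7,8-trimethoxyflavone	31.71	0.35	Huangqin
MOL000073	Ent-epicatechin	48.96	0.24	Huangqin
MOL000449	Stigmasterol	43.83	0.76	Huangqin
MOL001458	Coptisine	30.67	0.86	Huangqin
MOL001490	bis[(2S)-2-Ethylhexyl] benzene-1,2-dicarboxylate	43.59	0.35	Huangqin
MOL001506	Supraene	33.55	0.42	Huangqin
MOL002879	Diop	43.59	0.39	Huangqin
MOL002897	Epiberberine	43.09	0.78	Huangqin
MOL008206	Moslosooflavone	44.09	0.25	Huangqin
MOL010415	11,13-Eicosadienoic acid, methyl ester	39.28	0.23	Huangqin
MOL012245	5,7,4'-Trihydroxy-6-methoxyflavanone	36.63	0.27	Huangqin
MOL012246	5,7,4'-Trihydroxy-8-methoxyflavanone	74.24	0.26	Huangqin
MOL012266	Rivularin	37.94	0.37	Huangqin
MOL002935	Baicalin	29.53	0.77	Huangqin
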