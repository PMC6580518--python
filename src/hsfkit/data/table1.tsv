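name	gene_id	scaffold_label	start	end	est_count	length_bp	exons	introns	aa_length	pi	mw_kda
TaHsf1	Trae_4AL_8577C148B	scaffold_288809_4AL	49335	56655	26	7321	3	2	521	4.94	57.34
TaHsf2	Trae_5BL_E15759DAD	scaffold_404129_5BL	211116	217536	26	6421	2	1	471	5.18	52.89
TaHsf3	Trae_5DL_B1D24781B1	scaffold_433347_5DL	108916	114305	28	5390	2	1	487	4.95	54.60
TaHsf4	Trae_5AL_16AD8DEEC	scaffold_375092_5AL	45746	49544	4	3799	2	1	346	5.45	38.98
TaHsf5	Trae_5DL_6EB179C88	scaffold_434875_5DL	17703	21445	8	3743	2	1	348	5.39	38.90
TaHsf6	nd	scaffold_640974_U	63006	67190	6	4185	2	1	353	5.59	39.72
TaHsf7	Trae_2AS_CF07F4EC2	scaffold_113503_2AS	55860	61955	26	6096	2	1	413	4.99	45.60
TaHsf8	Trae_2BS_ECF9B4EB4	scaffold_148328_2BS	27356	32557	49	5202	2	1	405	5.06	44.92
TaHsf9	Trae_2DS_B6872CB84	scaffold_177319_2DS	131495	137254	27	5760	2	1	412	4.85	45.43
TaHsf10	Trae_3AL_E15419B88	scaffold_194616_3AL	22466	26620	2	4155	2	1	314	6.14	35.42
TaHsf11	TRAES3BF002300100CFD	scaffold_221589_3B	97736	102700	4	4965	3	2	396	5.09	43.99
TaHsf12	nd	scaffold_379543_5AL	6399	8897	10	2499	3	2	372	5.37	41.13
TaHsf13	nd	scaffold_433195_5DL	110106	113560	9	3455	2	1	377	5.42	41.59
TaHsf14	nd	scaffold_116363_2AS	3667	6615	7	2949	2	1	467	6.06	51.62
TaHsf15	Trae_2AS_53BFA14C7	scaffold_114504_2AS	30086	34710	7	4625	4	3	502	5.95	55.44
TaHsf16	Trae_2BS_1484A7516	scaffold_146118_2BS	176336	179440	7	3105	2	1	475	5.94	52.08
TaHsf17	Trae_2DS_070CE3D50	scaffold_177422_2DS	92871	96205	8	3335	2	1	499	5.70	54.78
TaHsf18	Trae_3AL_463ABD4BF	scaffold_196554_3AL	30462	32936	15	2475	2	1	432	5.36	48.37
TaHsf19	TRAES3BF029100010CFD	scaffold_223991_3B	37660	40120	15	2461	2	1	441	5.18	49.46
TaHsf20	Trae_3DL_8FD0F859B	scaffold_249383_3DL	45727	48075	16	2349	2	1	433	5.35	48.45
TaHsf21	Trae_1AL_7D6DC73FC	scaffold_001183_1AL	39381	43295	48	3915	3	2	448	4.91	50.25
TaHsf22	nd	scaffold_031159_1BL	70097	72255	9	2159	3	2	445	4.94	49.92
TaHsf23	nd	scaffold_061383_1DL	26931	29065	8	2135	3	2	442	5.11	49.70
TaHsf24	Trae_6AS_1537629B3	scaffold_487059_6AS	7273	11032	7	3760	2	1	458	5.21	49.87
TaHsf25	Trae_6BS_25E162197	scaffold_513816_6BS	34066	37539	8	3474	2	1	455	5.33	49.92
TaHsf26	Trae_6DS_C59B6322F	scaffold_543918_6DS	1556	5556	7	4001	2	1	458	5.16	49.86
TaHsf27	Trae_1AL_A4B5C1474	scaffold_003124_1AL	28946	32101	30	3156	5	4	368	5.00	41.70
TaHsf28	Trae_1BL_5D8D6B865	scaffold_031443_1BL	79599	83003	27	3405	4	3	364	4.89	41.02
TaHsf29	Trae_1DL_B5A84E4C8	scaffold_061579_1DL	62790	66102	29	3313	4	3	370	5.03	42.03
TaHsf30	Trae_4AS_52EB860E7	scaffold_307193_4AS	64786	67745	13	2960	2	1	341	5.07	39.63
TaHsf31	Trae_4BL_2E125A702	scaffold_321575_4BL	50126	53221	12	3096	2	1	341	5.07	39.59
TaHsf32	Trae_4DL_AF19ABC7D	scaffold_342984_4DL	44562	50805	13	6244	4	3	341	5.02	39.49
TaHsf33	nd	scaffold_559301_7AL	9972	11835	4	1864	5	4	310	4.67	33.78
TaHsf34	nd	scaffold_579527_7BL	16166	18111	5	1946	4	3	351	4.94	37.90
TaHsf35	nd	scaffold_605087_7DL	18736	21007	5	2272	4	3	351	4.82	37.98
TaHsf36	Trae_4AS_02B607421	scaffold_306492_4AS	132616	136430	10	3815	4	3	383	5.22	42.84
TaHsf37	Trae_4BL_542B1DA85	scaffold_322416_4BL	4327	8215	9	3889	4	3	384	5.30	42.87
TaHsf38	Trae_4DL_EE941086E	scaffold_344014_4DL	13486	17310	9	3825	4	3	384	5.30	42.92
TaHsf39	Trae_5AL_D369204D3	scaffold_374310_5AL	146720	151848	28	5129	2	1	298	9.50	32.14
TaHsf40	Trae_5BL_F80E01D65	scaffold_404669_5BL	141516	147139	27	5624	2	1	298	9.31	32.28
TaHsf41	Trae_5DL_431CCA490	scaffold_433651_5DL	31056	36542	28	5487	2	1	298	9.20	32.06
TaHsf42	Trae_2AL_D3B2C21A7	scaffold_094650_2AL	33644	35170	2	1527	2	1	295	6.12	31.99
TaHsf43	nd	scaffold_712376_U	1	715	1	1715	2	1	209	9.50	22.72
TaHsf44	nd	scaffold_019033_1AS	12760	16705	25	3946	3	2	404	4.90	42.04
TaHsf45	Trae_5BL_FCB1625F3	scaffold_404935_5BL	109416	113225	27	3810	3	2	701	9.22	73.92
TaHsf46	nd	scaffold_433530_5DL	41946	43807	26	1862	2	1	397	4.89	41.11
TaHsf47	Trae_7AS_937121AF8	scaffold_570040_7AS	14527	16335	6	1809	2	1	374	5.44	40.45
TaHsf48	Trae_7BS_03F39ED94	scaffold_592325_7BS	110144	112895	6	2752	3	2	374	5.33	40.33
TaHsf49	Trae_7DS_10A9C68FA	scaffold_621446_7DS	14666	16580	6	1915	2	1	367	5.50	39.79
TaHsf50	Trae_2DS_01A0E5F7A	scaffold_178567_2DS	15585	18518	4	2934	2	1	320	6.55	35.31
TaHsf51	nd	scaffold_642758_U	53288	55875	5	2587	2	1	320	6.66	35.26
TaHsf52	nd	scaffold_374067_5AL	30626	32510	7	1885	2	1	388	7.85	41.35
TaHsf53	nd	scaffold_404268_5BL	201437	203325	8	1889	2	1	388	7.89	41.46
TaHsf54	nd	scaffold_433663_5DL	11036	12824	8	1785	2	1	388	8.42	41.39
TaHsf55	nd	scaffold_201352_3AL	447	1655	0	1209	3	2	277	5.54	31.15
TaHsf56	nd	scaffold_194514_3AL	70656	72591	2	1936	2	1	294	6.26	32.57
TaHsf57	nd	scaffold_220888_3B	91006	92356	0	1351	2	1	322	5.46	35.55
TaHsf58	TRAES3BF021000010CFD	scaffold_220882_3B	116126	117715	2	1585	2	1	325	5.94	35.72
TaHsf59	nd	scaffold_249994_3DL	60736	62250	2	1515	2	1	321	6.16	35.38
TaHsf60	nd	scaffold_249450_3DL	110687	117555	16	6869	3	2	225	7.11	25.63
TaHsf61	nd	scaffold_193607_3AL	163384	164530	13	1147	2	1	236	6.91	26.05
TaHsf62	TRAES3BF005500020CFD	scaffold_223354_3B	26214	27330	14	1117	2	1	227	8.35	24.69
TaHsf63	nd	scaffold_250779_3DL	25456	26755	11	1300	2	1	241	8.76	26.40
TaHsf64	TRAES_3BF025700020CFD_c1	scaffold_231430_3B	2326	3400	4	1075	1	0	237	5.11	26.12
TaHsf65	nd	scaffold_223198_3B	70994	72095	2	1102	2	1	237	5.99	26.61
TaHsf66	TRAES3BF025700030CFD	scaffold_224063_3B	9915	11221	27	1307	1	0	274	6.98	29.98
TaHsf67	Trae_4BL_86572BB6D	scaffold_321958_4BL	10751	11969	9	1215	1	0	264	5.43	29.06
TaHsf68	Trae_4BL_F6C3B5069	scaffold_320289_4BL	21946	23120	25	1175	1	0	275	8.40	30.21
TaHsf69	Trae_4BL_5091DE58E	scaffold_320289_4BL	33386	34490	2	1105	1	0	257	4.88	28.50
TaHsf70	nd	scaffold_320675_4BL	112161	113540	5	1380	2	1	273	5.70	29.45
TaHsf71	nd	scaffold_344468_4DL	19506	20710	14	1205	1	0	276	6.46	30.27
TaHsf72	Trae_4DL_FA07D8414	scaffold_343739_4DL	22666	23885	4	1220	1	0	276	5.32	29.85
TaHsf73	nd	scaffold_376864_5AL	4896	6010	4	1115	1	0	273	6.15	30.17
TaHsf74	nd	scaffold_375679_5AL	69576	70900	15	1325	1	0	229	5.08	25.56
TaHsf75	nd	scaffold_641118_U	187271	188375	0	1105	2	1	268	5.69	29.99
TaHsf76	Trae_7AL_6931AA68B	scaffold_558532_7AL	22876	24495	13	1620	2	1	266	6.44	28.23
TaHsf77	nd	scaffold_577398_7BL	12506	14356	14	1851	2	1	244	5.61	26.12
TaHsf78	nd	scaffold_609477_7DL	1	1636	16	1636	2	1	263	6.11	28.04
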