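name	type	dbd_start	dbd_end	hr_start	hr_end	nls	nes	aha
TaHsf1	A1a	38	128	163	227	(245)RRIVAANKKRR	(508)LTEQMGLL	AHA2(464)DSFWEQFLCA
TaHsf2	A1a	1	73	109	173	(191)RRIVAANKKRR	(458)LTEQMGLL	AHA2(414)DSFWEQFLCA
TaHsf3	A1a	1	91	125	189	(207)RRIVAANKKRR	(474)LTEQMGLL	AHA2(430)DSFWEQFLCA
TaHsf4	A2a	38	128	143	207	(223)RKELEDAISNKRRRR	nd	AHA1(313)DDFWEDLL
TaHsf5	A2a	40	130	145	209	(225)RKELEDAISNKRRRR	nd	AHA1(315)DDFWEDLL
TaHsf6	A2a	45	135	150	214	(230)RKELEDAISNKRRRR	nd	AHA(320)DDFWEDLL
TaHsf7	A2b	43	133	149	213	(229)RKELHDAISKKRRRR	(400)KMGYL	AHA1(370)DNFWEELL
TaHsf8	A2b	44	134	150	214	(230)SKELHDAISKKRRRR	(392)KMGYF	AHA1(362)DNFWEGLL
TaHsf9	A2b	43	133	149	213	(229)RKELHDAISKKRRRR	(399)KMGYL	AHA1(369)DNFWEELL
TaHsf10	A2b	42	132	148	212	(228)RKELHDAMSKKRRRS	nd	nd
TaHsf11	A2b	41	131	147	211	(227)RKELHDAMSKKRRRS	nd	AHA1(353)DDFWEELM
TaHsf12	A2e	66	156	178	242	(260)RKELAEALLSKKRGR	nd	AHA1(314)ESFWKELL
TaHsf13	A2e	66	156	180	244	(262)RKELAEALLSKKRGR	nd	AHA1(320)ESFWKELL
TaHsf14	A3	49	139	175	221	(248)RVKRKFLKHV	nd	nd
TaHsf15	A3	84	174	210	256	(283)RVKRKFLKHV	nd	nd
TaHsf16	A3	80	170	206	252	(279)RVKRKFLKHV	nd	nd
TaHsf17	A3	81	171	207	253	(280)RVKRKFLKHV	nd	nd
TaHsf18	A4a	13	103	126	183	(198)KKRR	(419)MTEKLGHL	AHA1(244)LNSLENFFKE AHA2(370)DGFWQQFLTE
TaHsf19	A4a	13	103	126	183	(198)KKRR	(428)MTEKLGHL	AHA1(244)LNSLENFFKE AHA2(379)DGFWQQFLTE
TaHsf20	A4a	13	103	126	183	(198)KKRR	(420)MTKKLGHL	AHA1(244)LNSLENFFKE AHA2(370)DGFWQQFLTE
TaHsf21	A4d	25	115	138	195	(220)KKRR	(430)ITQQMGHL	AHA1(267)LVSMEKLVQR AHA2(386)DLFWERFLTD
TaHsf22	A4d	23	113	136	193	(219)KKRR	(432)ITEQMGHL	AHA1(267)LVSMEKLVRR AHA2(388)DLFWERFLTD
TaHsf23	A4d	23	113	136	193	(218)KKRR	(429)ITEQMGHL	AHA1(270)LVSMEKLVQR AHA2(385)DLFWERFLTD
TaHsf24	A5	20	111	131	188	(199)KMAEASSMFADALHKK	nd	(414)DNFWEQFLTE
TaHsf25	A5	20	111	131	188	(199)KMAEASSMFADALHKK	nd	(414)DNFWEQFLTE
TaHsf26	A5	20	111	131	188	(199)KMAEASSMFADALHKK	nd	(414)DNFWEQFLTE
TaHsf27	A6a	52	142	159	223	(238)KRKELEDAISKKRRR	(352)IDELGQQLGYL	(322)SDFWAELFSD
TaHsf28	A6a	48	138	155	219	(234)KRKELEDAISKKRRR	(348)IDELAQQLGYL	(318)NDFWAELFSD
TaHsf29	A6a	54	144	161	225	(240)KRKELEDAISKKRRR	(354)IDELAQQLGYL	(324)NDFWAELFSD
TaHsf30	A6b	46	136	153	217	(232)KLKDLEDGYPTKRRR	nd	(311)DDFWEELLSE
TaHsf31	A6b	46	136	153	217	(232)KLKDLEDGYPTKRRR	nd	(311)DDFWEELLSE
TaHsf32	A6b	46	136	153	217	(232)KLKDLEDAYSNKRRR	nd	(311)DDFWEELLSE
TaHsf33	A7b	47	138	150	175	nd	nd	(246)TDMIWYELL
TaHsf34	A7b	49	139	173	223	nd	nd	(298)TDMIWYELL
TaHsf35	A7b	49	139	173	223	nd	nd	(298)TDMIWYELL
TaHsf36	A8	37	127	173	230	nd	nd	nd
TaHsf37	A8	37	127	173	230	nd	nd	nd
TaHsf38	A8	37	127	173	230	nd	nd	nd
TaHsf39	B1	27	117	172	209	nd	nd	nd
TaHsf40	B1	30	120	174	211	nd	nd	nd
TaHsf41	B1	30	120	174	211	nd	nd	nd
TaHsf42	B2a	13	103	157	193	(223)KRSRE	nd	nd
TaHsf43	B2a	26	116	170	206	nd	nd	nd
TaHsf44	B2c	42	132	215	251	(321)KRARD	nd	nd
TaHsf45	B2c	176	266	349	385	(455)KRARD	nd	nd
TaHsf46	B2c	42	132	215	251	(321)KRARD	nd	nd
TaHsf47	B2d	32	122	192	228	(300)KRMRH	nd	nd
TaHsf48	B2d	32	122	192	228	(300)KRMRH	nd	nd
TaHsf49	B2d	32	122	192	228	(293)KRMRH	nd	nd
TaHsf50	B4b	40	130	201	237	(299)KKKR	nd	nd
TaHsf51	B4b	39	129	200	236	(299)KKKR	nd	nd
TaHsf52	B4c	26	117	207	243	(336)PVGA	(362)LALENDDL	nd
TaHsf53	B4c	26	117	207	243	(336)PVGA	(362)LALESDDL	nd
TaHsf54	B4c	26	117	207	243	(336)PVGA	(362)LALESDDL	nd
TaHsf55	C1a	21	111	121	164	nd	nd	nd
TaHsf56	C1a	1	84	121	171	nd	nd	nd
TaHsf57	C1a	21	111	154	197	nd	nd	nd
TaHsf58	C1a	25	115	159	202	nd	nd	nd
TaHsf59	C1a	25	115	159	202	nd	nd	nd
TaHsf60	C1a	21	111	149	192	nd	nd	nd
TaHsf61	C1b	19	109	126	169	nd	nd	nd
TaHsf62	C1b	19	109	131	174	nd	nd	nd
TaHsf63	C1b	19	109	131	174	nd	nd	nd
TaHsf64	C2a	1	75	97	140	(168)KRPR	nd	nd
TaHsf65	C2a	24	114	134	177	(202)KRPR	nd	nd
TaHsf66	C2a	19	109	132	175	(203)KRPR	nd	nd
TaHsf67	C2a	12	102	124	167	(195)QRPR	nd	nd
TaHsf68	C2a	21	111	135	178	(206)KRPR	nd	nd
TaHsf69	C2a	20	110	132	175	(203)KKPR	nd	nd
TaHsf70	C2a	24	114	135	178	(205)KRPR	nd	nd
TaHsf71	C2a	23	113	135	178	(206)KRRR	nd	nd
TaHsf72	C2a	24	114	141	184	(211)KRPR	nd	nd
TaHsf73	C2a	30	120	143	186	(207)NRPR	nd	nd
TaHsf74	C2a	1	84	106	149	(177)KRPR	nd	nd
TaHsf75	C2a	23	113	132	175	(198)KRLR	nd	nd
TaHsf76	C2b	15	105	132	175	(204)KRAR	nd	nd
TaHsf77	C2b	1	84	97	153	nd	nd	nd
TaHsf78	C2b	13	103	129	172	(201)KRAR	nd	nd
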