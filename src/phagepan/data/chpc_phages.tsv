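phage_id	host_strains	group	year	country	product	genome_size	n_orfs	gc	accession
CHPC1005	STCH_12	cos	2003	France	cheese	37598	49	38	MH937483
CHPC1008	STCH_09 STCH_43	pac	2003	France	cheese	34844	48	40	MH937484
CHPC1014	STCH_13	cos	2003	USA	cheese	35260	49	38	MH937485
CHPC1027	STCH_12	cos	2004	Italy	cheese	35928	48	38	MH937486
CHPC1029	STCH_13	cos	2004	Italy	cheese	35920	47	39	MH937487
CHPC1033	STCH_12	cos	2004	Italy	cheese	36827	49	38	MH937488
CHPC1034	STCH_13	cos	2004	Italy	cheese	33826	42	39	MH937489
CHPC1036	STCH_18	cos	2004	Italy	cheese	36333	50	38	MH937490
CHPC1037	STCH_34	cos	2005	USA	cheese	36551	46	38	MH937491
CHPC1040	STCH_13	cos	2005	Italy	cheese	35851	47	38	MH937492
CHPC1041	STCH_38	cos	2005	Italy	cheese	38840	55	38	MH937493
CHPC1042	STCH_07	pac	2005	Italy	cheese	42019	63	39	MH937494
CHPC1045	STCH_40	cos	2005	USA	cheese	34096	46	38	MH937495
CHPC1046	STCH_14 STCH_39	cos	2005	USA	cheese	34790	48	38	MH937496
CHPC1048	STCH_14 STCH_39	cos	2005	USA	cheese	34812	48	38	MH937497
CHPC1057	STCH_09 STCH_43	pac	2005	France	yoghurt	34845	47	40	MH937498
CHPC1062	STCH_31	cos	2005	France	cheese	40037	56	38	MH937499
CHPC1067	STCH_12	cos	2005	France	cheese	34355	45	39	MH937500
CHPC1073	STCH_12	cos	2006	France	cheese	34017	47	38	MH937501
CHPC1083	STCH_12	pac	2006	USA	cheese	36471	48	39	MH937502
CHPC1084	STCH_13	pac	2006	USA	cheese	36776	49	39	MH937503
CHPC1091	STCH_04	cos	2006	France	yoghurt	37028	49	38	MH937504
CHPC1109	STCH_36	pac	2006	USA	cheese	33791	47	39	MH937505
CHPC1148	STCH_41	cos	2008	Germany	cheese	39069	52	38	MH937506
CHPC1152	STCH_06	pac	2008	France	yoghurt	35353	47	39	MH937507
CHPC1156	STCH_19	cos	2009	USA	cheese	34912	48	38	MH937508
CHPC1230	STCH_45	pac	2012	USA	cheese	39384	57	39	MH937509
CHPC1246	STCH_07	pac	2013	USA	cheese	36876	55	39	MH937510
CHPC1247	STCH_07	pac	2013	France	cheese	35543	50	39	MH937511
CHPC1248	STCH_07	pac	2013	France	cheese	38383	56	39	MH937457
CHPC572	STCH_24	cos	N/A	Italy	cheese	37005	51	38	MH937458
CHPC595	STCH_25	cos	N/A	Argentina	cheese	35697	49	39	MH937459
CHPC640	STCH_26 STCH_28	pac	N/A	Italy	cheese	40404	57	38	MH937460
CHPC642	STCH_17	cos	N/A	Italy	cheese	35715	52	38	MH937461
CHPC663	STCH_29	cos	1995	Italy	cheese	38531	54	38	MH937462
CHPC676	STCH_26 STCH_28	pac	N/A	Italy	cheese	40402	55	38	MH937463
CHPC869	STCH_44	pac	1998	France	yoghurt	37080	52	39	MH937464
CHPC873	STCH_42	cos	1998	France	cheese	38258	53	38	MH937465
CHPC875	STCH_23	cos	1998	France	cheese	36576	51	39	MH937466
CHPC877	STCH_32 STCH_33	cos	1998	France	cheese	39965	54	38	MH937467
CHPC879	STCH_20	cos	1998	France	cheese	36011	48	38	MH937468
CHPC919	STCH_37	cos	2000	France	cheese	37281	48	38	MH937469
CHPC925	STCH_21	cos	2000	France	cheese	34759	47	38	MH937470
CHPC927	STCH_32 STCH_33	cos	2000	France	cheese	37303	50	38	MH937471
CHPC928	STCH_22	cos	2000	France	cheese	34022	43	38	MH937472
CHPC929	STCH_35	pac	2000	France	cheese	40874	60	38	MH937473
CHPC930	STCH_30	cos	2000	France	cheese	36350	49	38	MH937474
CHPC931	STCH_44	pac	2000	France	yoghurt	36490	51	39	MH937475
CHPC933	STCH_02	pac	2001	France	yoghurt	32182	40	40	MH937476
CHPC950	STCH_13	cos	2002	UK	cheese	35299	52	39	MH937477
CHPC951	STCH_12	pac	2002	USA	cheese	36471	49	39	MH937478
CHPC952	STCH_13	pac	2002	USA	cheese	36775	49	39	MH937479
CHPC954	STCH_27	cos	2002	USA	cheese	37464	47	38	MH937480
CHPC979	STCH_13	cos	2002	Germany	cheese	34277	50	38	MH937481
CHPC982	STCH_13	cos	2002	France	cheese	35246	48	38	MH937482
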