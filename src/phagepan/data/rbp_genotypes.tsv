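rbp_cluster	phage_id	host_strain	eps_genotype	rgp_genotype
I	CHPC979	STCH_13	A	C
I	CHPC982	STCH_13	A	C
I	CHPC1041	STCH_38	A	A
II	CHPC954	STCH_27	A	C
II	CHPC1037	STCH_34	A	C
II	CHPC572	STCH_24	D	B
II	CHPC877	STCH_32	D	B
II	CHPC927	STCH_33	D	B
II	CHPC1014	STCH_13	A	C
II	CHPC1029	STCH_13	A	C
II	CHPC1034	STCH_13	A	C
II	CHPC1040	STCH_13	A	C
II	CHPC950	STCH_13	A	C
II	CHPC1148	STCH_41	A	C
II	CHPC1046	STCH_39	D	C
II	CHPC1048	STCH_14	D	C
III	CHPC1005	STCH_12	C	A
III	CHPC1027	STCH_12	C	A
III	CHPC1033	STCH_12	C	A
III	CHPC1067	STCH_12	C	A
III	CHPC1073	STCH_12	C	A
III	CHPC1156	STCH_19	C	B
III	CHPC879	STCH_20	B	A
III	CHPC925	STCH_21	B	A
IV	CHPC930	STCH_30	A	A
IV	CHPC642	STCH_17	C	D
IV	CHPC1036	STCH_18	C	D
V	CHPC933	STCH_02	F	A
V	CHPC640	STCH_28	C	B
V	CHPC676	STCH_28	C	B
VI	CHPC1152	STCH_06	A	A
VI	CHPC1008	STCH_09	D	C
VI	CHPC1057	STCH_09	D	C
VII	CHPC1083	STCH_12	C	A
VII	CHPC951	STCH_12	C	A
VII	CHPC1084	STCH_13	A	C
VII	CHPC952	STCH_13	A	C
VII	CHPC869	STCH_44	E	C
VII	CHPC931	STCH_44	E	C
VII	CHPC1042	STCH_07	C	E
VII	CHPC1246	STCH_07	C	E
VII	CHPC1247	STCH_07	C	E
VII	CHPC1248	STCH_07	C	E
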