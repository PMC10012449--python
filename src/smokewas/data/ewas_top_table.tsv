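locus	cpg_id	coefficient	t_value	p_value	chromosome	position	fdr	gene	bmd_association
1	cg03009196	9.97E-06	6.35	1.20E-06	1	60392511	0.022	CYP2J2	Yes
2	cg22010000	-1.01E-05	-8.55	6.89E-09	1	151738555	0.002	OAZ3	Yes
3	cg08901901	8.25E-06	8.04	2.14E-08	1	160951907	0.002		No
4	cg25619551	-9.25E-06	-6.59	6.62E-07	1	193710042	0.015		No
5	cg15073625	-5.60E-06	-5.88	3.90E-06	2	23862014	0.047	KLHL29	Yes
6	cg10565322	-8.49E-06	-6.46	9.15E-07	2	43136493	0.017		Yes
7	cg17641218	-9.64E-06	-7.78	3.87E-08	2	85804603	0.002	VAMP8	Yes
8	cg02494004	-8.62E-06	-6.35	1.21E-06	2	147162808	0.022		Yes
9	cg06342954	-8.24E-06	-6.34	1.24E-06	2	236757889	0.022	AGAP1	Yes
10	cg14485214	-7.96E-06	-7.23	1.42E-07	2	241957552	0.005	SNED1	Yes
11	cg00227784	-7.62E-06	-8.76	4.33E-09	3	126391755	0.002		Yes
12	cg14379327	-6.77E-06	-7.54	6.87E-08	4	146404134	0.003	SMAD1	Yes
13	cg20093868	-8.86E-06	-5.85	4.27E-06	4	152646689	0.049	GATB	No
14	cg09865379	-7.61E-06	-5.94	3.35E-06	4	165708173	0.042	LINC01207	No
15	cg06753918	-5.91E-06	-6	2.89E-06	5	6182215	0.038		No
16	cg16653901	-9.45E-06	-6.27	1.48E-06	5	133513511	0.025	SKP1	No
17	cg01247535	1.03E-05	6.72	4.89E-07	6	15418354	0.012	JARID2	No
18	cg17866778	-1.58E-05	-6.51	8.05E-07	6	26233442	0.017		Yes
19	cg06501109	-1.23E-05	-6.08	2.37E-06	6	30850309	0.033	DDR1	Yes
20	cg17774634	-9.25E-06	-7.83	3.45E-08	6	97730494	0.002	C6orf167;MIR548H3	No
21	cg05923369	-1.04E-05	-6.47	8.93E-07	7	2251548	0.017	MAD1L1	No
22	cg24648241	-9.54E-06	-5.98	3.01E-06	7	38347775	0.039		No
23	cg14355428	-9.62E-06	-8.56	6.76E-09	7	91762876	0.002	CYP51A1	Yes
24	cg02396891	-6.61E-06	-6.3	1.36E-06	7	93222734	0.023		No
25	cg10333170	-9.21E-06	-5.91	3.66E-06	7	134521311	0.046	CALD1	No
26	cg22859658	-2.03E-05	-7.77	4.00E-08	7	144422735	0.002	TPK1	No
27	cg10993470	-1.05E-05	-6.03	2.66E-06	8	55533939	0.036	RP1	No
28	cg23855920	-9.03E-06	-6.24	1.58E-06	8	103764916	0.026		No
29	cg24529650	-1.02E-05	-7.24	1.38E-07	9	14031418	0.005		No
30	cg13396858	-1.05E-05	-5.89	3.85E-06	9	134249466	0.047		Yes
31	cg00013660	-8.96E-06	-7.6	5.95E-08	9	140068770	0.003		Yes
32	cg12368066	-1.37E-05	-6.93	2.88E-07	10	9449275	0.008		No
33	cg00762372	-6.16E-06	-6.19	1.79E-06	10	25618736	0.027	GPR158	No
34	cg13820475	-9.93E-06	-6.46	9.19E-07	10	44461659	0.017	LINC00841	No
35	ch.10.107354959F	-9.33E-06	-6.53	7.69E-07	10	107364969	0.017		No
36	cg02701677	-8.07E-06	-7.46	8.30E-08	11	23970707	0.003		No
37	cg08086799	-1.20E-05	-6.9	3.12E-07	11	62495467	0.009	TTC9C;HNRNPUL2	Yes
38	cg22968863	-1.03E-05	-7.51	7.23E-08	11	72441739	0.003	ARAP1	No
39	cg20199739	1.88E-05	7.03	2.30E-07	11	107730522	0.007	SLC35F2	No
40	cg04932413	-1.54E-05	-6.76	4.33E-07	14	103002828	0.011	KLC1	Yes
41	cg01279902	-1.01E-05	-8.12	1.79E-08	14	104171040	0.002	XRCC3	Yes
42	cg04662961	-6.63E-06	-6.11	2.21E-06	15	44486562	0.031	FRMD5	Yes
43	cg27111704	-7.75E-06	-6.52	7.95E-07	15	83847628	0.017	HDGFRP3	No
44	cg16362027	-7.71E-06	-5.86	4.10E-06	15	88856288	0.048		No
45	cg22581270	-7.20E-06	-7.01	2.39E-07	16	3193156	0.007	CASP16P	Yes
46	cg03660158	9.88E-06	6.19	1.77E-06	16	57769342	0.027	KATNB1	Yes
46	cg00122310	1.30E-05	7.79	3.84E-08	16	57769432	0.002
46	cg00439196	1.48E-05	8.09	1.93E-08	16	57769757	0.002
46	cg06830769	1.14E-05	8.07	2.02E-08	16	57769885	0.002
47	cg21854895	-1.06E-05	-7.92	2.81E-08	17	71305638	0.002	CDC42EP4	Yes
48	cg06400109	8.45E-06	6.18	1.83E-06	17	76183118	0.027	AFMID;TK1	Yes
48	cg07246050	8.44E-06	6.86	3.44E-07	17	76183123	0.009	AFMID;TK1
49	cg21441526	-9.09E-06	-7.46	8.11E-08	18	21516439	0.003	LAMA3	No
50	cg26258423	-7.60E-06	-6.22	1.67E-06	18	75380233	0.027		No
51	cg27071707	-7.31E-06	-7.83	3.49E-08	19	1614334	0.002	TCF3	Yes
52	cg18788725	-7.34E-06	-6.07	2.40E-06	19	45512122	0.033	RELB	No
53	cg04700648	-1.03E-05	-6.14	2.01E-06	19	52888958	0.029	ZNF880	No
54	cg05325193	8.85E-06	6.86	3.47E-07	20	22558233	0.009	C20orf56	No
55	cg25580335	-9.10E-06	-7.1	1.93E-07	22	24738240	0.006	SPECC1L	No
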