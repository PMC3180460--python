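rank	chrom	snp_pos	lsp_distance	ncogc_total	n13	n31	flank_left	flank_right	co_total	ratio	kb_per_cm	nonparity
1	1	207154	4377	24	2	22	202364	224761	4	6.0	2.87	1
2	16	727489	284786	18	10	8	726624	730555	5	3.6	0.23	0
3	10	219325	16016	13	13	0	218051	220352	1	13.0	3.06	1
4	6	35896	19112	12	6	6	32870	36516	2	6.0	3.63	0
5	9	55057	150587	12	8	4	48869	65509	21	0.6	0.71	0
6	10	705481	502172	12	6	6	698817	705760	13	0.9	1.23	0
7	15	987472	85823	12	6	6	985916	989604	8	1.5	0.47	0
8	8	506124	411190	11	6	5	469077	522577	43	0.3	1.89	0
9	11	492956	55920	11	7	4	491888	494246	1	11.0	2.56	0
10	16	426495	10789	11	8	3	396191	428320	23	0.5	3.16	0
11	6	226159	20245	10	5	5	207830	228481	49	0.2	0.83	0
12	6	245474	39560	10	4	6	234568	258527	19	0.5	1.38	0
13	9	166164	39480	10	3	7	164868	167620	1	10.0	3.11	0
14	15	71614	60585	10	5	5	68376	74107	6	1.7	0.78	0
15	2	46708	218793	9	3	6	40974	118939	13	0.7	1.06	0
16	7	167431	234908	9	3	6	165776	171277	1	9.0	3.97	0
17	8	123594	28660	9	3	6	121713	125757	6	1.5	0.75	0
18	9	266704	34005	9	5	4	260006	268168	6	1.5	2.68	0
19	13	168927	NA	9	4	5	168076	174961	3	3.0	0.68	0
20	15	340372	329343	9	2	7	338394	340732	0	>9.0	>4.76	0
21	15	830761	242534	9	6	3	801267	831037	38	0.2	1.86	0
22	3	246792	61433	8	5	3	244165	249279	9	0.9	0.70	0
23	4	316797	NA	8	3	5	308239	316841	11	0.7	1.87	0
24	7	293241	109098	8	4	4	286692	293253	1	8.0	15.72	0
25	8	141666	46732	8	4	4	139384	142275	3	2.7	1.83	0
26	9	47640	158004	8	4	4	45971	48869	3	2.7	1.34	0
27	9	96848	108796	8	6	2	91092	99744	8	1.0	1.73	0
28	11	580437	NA	8	5	3	578505	580474	0	>8.0	>4.64	0
29	11	630662	NA	8	3	5	628758	631654	8	1.0	0.57	0
30	13	79932	NA	8	6	2	64448	79936	13	0.6	2.86	0
31	14	77011	691	8	5	3	72709	77160	3	2.7	3.44	0
32	14	180729	102603	8	3	5	161254	184130	11	0.7	4.25	0
33	15	177004	165975	8	2	6	176456	177722	1	8.0	1.32	0
34	15	602243	471052	8	6	2	601743	603028	5	1.6	0.24	0
35	16	47122	29610	8	3	5	44104	52999	9	0.9	0.80	0
36	1	196098	2768	7	7	0	190132	198648	34	0.2	0.42	1
37	2	193537	71964	7	3	4	191518	198087	9	0.8	0.54	0
38	2	290464	24277	7	5	2	280672	302383	22	0.3	1.07	0
39	5	26041	15934	7	5	2	24894	26667	2	3.5	1.38	0
40	5	43058	32951	7	3	4	39169	46317	8	0.9	1.17	0
41	7	407444	2787	7	3	4	405424	408707	1	7.0	4.85	0
42	7	731074	18833	7	4	3	730219	734615	0	>7.0	>2.05	0
43	8	121713	26779	7	3	4	105511	123594	9	0.8	4.32	0
44	8	289016	194082	7	3	4	286229	290523	2	3.5	3.34	0
45	9	268168	32541	7	3	4	266704	272654	3	2.3	1.17	0
46	9	375196	59180	7	2	5	362705	378374	9	0.8	3.33	0
47	10	188446	9391	7	4	3	184143	191363	5	1.4	2.07	0
48	10	316435	113126	7	3	4	313728	319675	9	0.8	0.72	0
49	11	166676	NA	7	4	3	165239	167774	6	1.2	0.57	0
50	12	40540	NA	7	3	4	35464	42230	13	0.5	0.94	0
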