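# Discovery-cohort statistics of the 31-peptide HCC marker panel, transcribed
# from the source publication's marker table (per-group all-sample mean signal
# amplitude (ion counts), SD, and detection frequency in %; Wilcoxon and
# Spearman p-values are BH-adjusted as printed).
# Groups: NONLC = non-cirrhotic controls (n=26), LC = liver cirrhosis (n=25),
# HCC = hepatocellular carcinoma (n=18).
peptide_id	p_adj_wilcoxon	auc	rho	p_adj_rho	mean_nonlc	sd_nonlc	freq_nonlc	mean_lc	sd_lc	freq_lc	mean_hcc	sd_hcc	freq_hcc
54	8.34e-03	0.70	0.353	1.43e-02	2	10	4	7	28	12	53	85	56
1059	4.57e-02	0.63	0.303	4.06e-02	4	18	8	3	13	12	30	55	33
1160	4.23e-02	0.63	0.431	1.83e-03	1	4	8	34	46	48	61	81	67
1778	1.50e-02	0.65	0.407	3.66e-03	5	26	4	18	34	32	29	40	50
2314	2.92e-02	0.65	0.385	6.52e-03	1911	3077	42	2696	2346	80	3017	2222	94
3559	1.30e-02	0.63	0.396	4.97e-03	47	88	31	184	223	60	201	224	67
3662	8.27e-04	0.76	0.489	3.08e-04	76	91	62	161	188	76	256	177	89
4564	6.81e-03	0.72	0.479	4.18e-04	270	130	92	639	579	96	591	449	94
4610	2.50e-03	0.65	0.398	4.74e-03	0	0	0	64	157	16	166	272	39
4829	1.54e-02	0.66	0.409	3.49e-03	59	142	27	277	358	76	245	286	67
5284	5.61e-03	0.70	0.362	1.15e-02	63	102	42	81	137	44	172	174	67
6601	3.57e-06	0.72	0.470	5.54e-04	0	0	0	1	4	4	199	286	44
6607	8.67e-04	0.65	0.380	7.39e-03	0	0	0	19	83	8	259	737	33
8720	6.37e-04	0.75	-0.587	8.05e-06	658	664	73	231	641	48	31	98	11
9080	3.34e-02	0.65	0.391	5.69e-03	813	2125	15	893	1236	48	1618	1815	61
9510	5.03e-03	0.72	0.370	9.56e-03	2227	4587	31	2847	4477	68	4563	3380	83
9728	1.90e-03	0.73	0.511	1.51e-04	345	745	23	902	1038	56	1359	916	89
10177	3.24e-03	0.71	0.358	1.29e-02	162	288	38	170	224	48	476	376	89
11725	6.63e-04	0.65	0.385	6.64e-03	0	0	0	4	12	8	28	50	33
12459	8.13e-06	0.86	-0.526	8.68e-05	373	152	96	335	236	92	119	124	61
13134	7.85e-04	0.73	0.311	3.45e-02	32	73	27	170	375	24	364	411	67
13176	1.20e-03	0.73	0.410	3.47e-03	27	54	27	103	190	40	171	155	72
14389	5.32e-04	0.74	-0.400	4.53e-03	53	64	54	20	37	40	0	0	0
14925	7.69e-04	0.73	-0.567	1.82e-05	689	1120	58	237	627	32	0	0	0
15342	1.38e-04	0.80	-0.604	3.66e-06	766	308	100	420	323	76	224	219	78
17066	1.33e-04	0.66	0.397	4.89e-03	0	3	4	8	53	4	257	693	33
17805	8.75e-04	0.75	-0.514	1.37e-04	394	478	69	235	349	52	16	36	22
19681	5.57e-04	0.76	-0.630	1.14e-06	127	129	85	34	53	40	9	21	17
20237	1.82e-04	0.79	0.483	3.69e-04	292	480	35	316	635	56	940	1064	94
24328	2.07e-05	0.84	-0.636	8.84e-07	5557	3207	100	2341	2674	100	890	1187	72
29919	1.20e-02	0.69	0.465	6.63e-04	199	505	23	525	661	60	857	1223	78
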