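# Sequence annotation of the 31-peptide HCC marker panel, transcribed from the
# source publication's sequencing table: experimental monoisotopic mass (Da),
# CE migration time (min), parent protein, 1-based amino-acid span, sequence
# with up to 4-residue N-/C-terminal flanking regions, and the curated
# protease associations of the terminal cleavage motifs.
# Lowercase p = hydroxyproline, lowercase m = oxidized methionine. Four
# peptides (1059, 9510, 12459, 20237) were not sequence-identified and carry
# empty sequence fields. Empty flank = protein terminus.
peptide_id	exp_mass	ce_time	protein	aa_start	aa_end	sequence	n_flank	c_flank	proteases_n	proteases_c
54	807.39	23.2	CLU	366	371	FNWVSR	LNEQ	LANL
1059	920.34	21.2
1160	928.51	24.6	UMOD	592	599	VIDQSRVL	RSGS	NLGP	MEP1A;MMP3	MEP1A;KLK6;CTSB;CTSD;CTSE
1778	981.49	24.4	ACTB	107	115	LTEAPLNPK	HPVL	ANRE	MEP1A;MMP3;MMP13;CTSB;CTSD;CTSE
2314	1032.45	25.9	ACTB	95	103	RVAPEEHPV	YNEL	LLTE		MEP1A;MMP3;MMP13;CTSB;CTSD;CTSE
3559	1134.59	24.0	COL3A1	755	766	PGKDGPRGPTGP	ADGV	IGPP
3662	1142.55	22.0	ADGRF3	56	64	NERIDRPFP	DKAW	ACPI
4564	1199.55	20.8	TKT	343	352	KNSTFSEIFK	DGDT	KEHP
4610	1201.53	24.9	GAGE12H	58	70	KGEDEGASAGQGP	AAAQ	KPEA	MEP1A;MMP3;CTSB	MMP3
4829	1217.48	27.7	COL3A1	179	191	pGPpGPpGTSGHp	PAGP	GSPG		KLK6;CTSB
5284	1250.64	20.6	HBB	136	147	AGVANALAHKYH	QKVV
6601	1352.78	22.0	AHNAK	772	784	NLPKADVDISGPK	EVDV	IDVT		MEP1A;KLK6
6607	1353.53	23.8	FGA	605	617	DEAGSEADHEGTH	YKMA	STKR	MEP1A
8720	1513.62	29.5	CDH1	397	410	KVTDADAPNTPAWE	ITTL	AVYT
9080	1539.74	40.4	COL18A1	1400	1416	GPpGPpGPPGPPSFPGP	EGRQ	HRQT	MEP1A;CTSB	MMP3
9510	1576.68	44.9
9728	1594.77	40.3	COL1A1	1177	1194	VGPpGPpGPpGPpGPPSA	DAGP	GFDF	MMP3	MMP3;MMP13;CTSB
10177	1624.73	25.1	COL2A1	1150	1167	DQGASGpAGpSGpRGPpG	GPSG	PVGP
11725	1733.73	29.8	GSN	605	621	WVGTGASEAEKTGAQEL	AAYL	LRVL	CTSD	MEP1A;MMP3;CTSD;CTSE
12459	1782.85	26.0
13134	1836.79	31.1	COL1A2	918	937	NGApGEAGRDGNPGNDGPpG	SPGV	RDGQ	MMP3	MEP1A;MMP3;MMP13;CTSB
13176	1840.83	41.9	COL2A1	1193	1213	SGETGPAGppGNPGPPGPpGP	PRGR	PGPG	MEP1A;KLK6	KLK6
14389	1930.89	31.6	COL3A1	618	639	GPpGPTGPGGDKGDTGPpGPQG	TGPQ	LQGL	MEP1A;CTSB	MEP1A;MMP3;MMP13;CTSB
14925	1972.96	25.0	PCSK1N	223	241	DHDVGSELPPEGVLGALLR	RRAA	VKRL	MEP1A	MEP1A;MMP3;MMP13
15342	2009.88	32.4	COL5A2	136	157	SKGEAGpTGPmGDpGTVGPPGP	GAPG	VGER	MEP1A;MMP3;MMP13;CTSB	MMP3
17066	2169.98	33.7	COL16A1	1145	1166	NSGEKGDQGFQGQPGFpGPPGP	GPQG	PGFP	MEP1A;MMP3;MMP13;CTSB
17805	2232.00	33.6	COL5A1	999	1021	VGpQGpTGETGpMGERGHPGPpG	PPGV	PPGE		MEP1A;CTSB
19681	2380.08	35.8	COL3A1	201	228	GPPGEPGQAGpSGpPGppGAIGPSGPAG	PGYQ	KDGE	MEP1A;CTSB	MEP1A;MMP3;MMP13;CTSB
20237	2430.60	35.7
24328	2854.37	34.6	COL3A1	616	646	PQGPpGPTGpGGDKGDTGPpGPQGLQGLpGT	GETG	GGPP	CTSB	MEP1A;CTSB
29919	3524.75	32.4	CLU	390	423	ASHTSDSDVPSGVTEVVVKLFDSDPITVTVPVEV	VTTV	SRKN		MMP3
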