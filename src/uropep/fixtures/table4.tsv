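# Per-group protease-activity surrogate statistics, transcribed from the
# source publication's protease table: mean +/- SD of the per-patient average
# substrate-peptide ion counts in the HCC case group (n=18) and the non-HCC
# liver-disease control group (n=51), the case/control fold change, and the
# Mann-Whitney U p-value. '<0.0001' is encoded as 0.0001 in p_upper_bound
# with p left empty.
protease	case_mean	case_sd	control_mean	control_sd	fold_change	p	p_upper_bound
MEP1A	196.23	93.19	365.65	231.12	0.54	0.003
MMP3	632.99	317.56	393.63	331.29	1.60	0.007
MMP13	729.36	402.76	495.03	539.78	1.47	0.012
KLK6	166.40	79.87	67.09	88.51	2.47		0.0001
CTSB	347.63	173.67	643.77	399.10	0.53	0.004
CTSD	32.90	33.44	17.35	31.21	1.89	0.015
CTSE	34.41	31.99	22.56	41.25	1.52	0.031
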