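organ	gene	mean_bb	mean_bc	mean_cc	se	n	anova_p	differences
liver	Ly75	1.00	1.81	3.19	0.17	5	0.0000037	C/C > B/C > B/B
liver	Pla2r1	1.00	-1.58	0.58	0.66	5	0.037	B/B ≥ C/C ≥ B/C
liver	Tank	1.00	2.24	-3.24	2.12	5	0.20	NA
liver	Fap	1.00	5.89	8.03	0.56	5	0.0000042	C/C > B/C > B/B
liver	Gca	1.00	0.79	0.34	0.03	5	0.000000037	B/B ≥ B/C ≥ C/C
WAT	Fap	1.00	1.43	2.11	0.06	5	0.00000018	C/C > B/C > B/B
WAT	Ifih1	1.00	-0.47	-0.53	0.31	3	0.023	B/B > B/C ≥ C/C
WAT	Grb14	1.00	0.73	0.50	0.09	5	0.0066	B/B ≥ B/C ≥ C/C
WAT	Cobll1	1.00	-0.85	-0.15	0.80	3	0.32	NA
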