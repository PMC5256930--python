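organ	gene	start	end	fpkm_cc	fpkm_bc	fpkm_bb	log2fc_cc_bb_printed	log2fc_bc_bb_printed
liver	Ly75	60286265	60383285	1.25	0.41	0.18	2.77	1.16
liver	Pla2r1	60415065	60553308	0.34	0.82	0.59	-0.79	0.47
liver	Tank	61578585	61654183	11.12	8.86	7.14	0.64	0.31
liver	Fap	62500715	62575559	0.32	0.20	0.06	2.32	1.64
liver	Gca	62664298	62695843	0.43	1.02	1.24	-1.52	-0.28
WAT	Fap	62500715	62575559	4.83	3.65	2.20	1.13	0.73
WAT	Ifih1	62593332	62646255	2.17	2.68	3.70	-0.77	-0.47
WAT	Grb14	64912468	65022766	2.50	4.84	5.84	-1.22	-0.27
WAT	Cobll1	65088183	65240557	0.14	0.33	0.23	-0.67	0.53
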