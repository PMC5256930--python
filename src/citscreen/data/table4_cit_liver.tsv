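trait	gene	p2	p3	p4	label	p3_marginal
Body weight at 10 weeks (g)	Ly75	0.000083	0.60	0.36		False
Body weight at 10 weeks (g)	Pla2r1	0.071	NA	NA		False
Body weight at 10 weeks (g)	Fap	0.00021	0.60	0.80		False
Body weight at 10 weeks (g)	Gca	0.00000089	0.88	0.27		False
Body weight at 14 weeks (g)	Ly75	0.00013	0.67	0.098		False
Body weight at 14 weeks (g)	Pla2r1	0.075	NA	NA		False
Body weight at 14 weeks (g)	Fap	0.00044	1.00	0.30		False
Body weight at 14 weeks (g)	Gca	0.0000013	0.82	0.068		False
Weight gain at 6-10 weeks (g)	Ly75	0.00040	0.13	0.83		False
Weight gain at 6-10 weeks (g)	Pla2r1	0.037	0.47	0.017	Independent	False
Weight gain at 6-10 weeks (g)	Fap	0.00040	0.19	0.74		False
Weight gain at 6-10 weeks (g)	Gca	0.0000042	0.14	0.60		False
Total body length (cm)	Ly75	0.000025	0.72	0.14		False
Total body length (cm)	Pla2r1	0.018	0.16	0.023	Independent	False
Total body length (cm)	Fap	0.000015	0.22	0.076		False
Total body length (cm)	Gca	0.00000031	0.63	0.13		False
Epididymal WAT weight (g)	Ly75	0.000087	0.057	0.32	Causal	True
Epididymal WAT weight (g)	Pla2r1	0.058	NA	NA		False
Epididymal WAT weight (g)	Fap	0.000025	0.088	0.083		False
Epididymal WAT weight (g)	Gca	0.00000079	0.36	0.20		False
Testes weight (g)	Ly75	0.000023	0.38	0.025	Independent	False
Testes weight (g)	Pla2r1	0.28	NA	NA		False
Testes weight (g)	Fap	0.00013	0.088	0.10		False
Testes weight (g)	Gca	0.00000022	0.30	0.020	Independent	False
LDL-C (mg/g)	Ly75	0.000029	0.27	0.13		False
LDL-C (mg/g)	Pla2r1	0.025	0.23	0.025	Independent	False
LDL-C (mg/g)	Fap	0.000062	0.92	0.26		False
LDL-C (mg/g)	Gca	0.0000000016	0.00071	0.00050		False
% Testes weight	Ly75	0.000089	0.44	0.000631	Independent	False
% Testes weight	Pla2r1	0.073	NA	NA		False
% Testes weight	Fap	0.0021	0.035	0.011		False
% Testes weight	Gca	0.00000051	0.20	0.00032	Independent	False
% Inguinal WAT weight	Ly75	0.000055	0.015	0.21	Causal	False
% Inguinal WAT weight	Pla2r1	0.013	0.10	0.011	Independent	False
% Inguinal WAT weight	Fap	0.00027	0.46	0.93		False
% Inguinal WAT weight	Gca	0.00000069	0.35	0.18		False
% Epididymal WAT weight	Ly75	0.00054	0.058	0.78	Causal	True
% Epididymal WAT weight	Pla2r1	0.043	0.47	0.014	Independent	False
% Epididymal WAT weight	Fap	0.00015	0.10	0.20		False
% Epididymal WAT weight	Gca	0.0000027	0.41	0.27		False
% Total WAT weight	Ly75	0.00024	0.025	0.58	Causal	False
% Total WAT weight	Pla2r1	0.025	0.22	0.014	Independent	False
% Total WAT weight	Fap	0.00030	0.24	0.66		False
% Total WAT weight	Gca	0.0000015	0.37	0.25		False
% CM-TG	Ly75	0.000093	0.62	0.23		False
% CM-TG	Pla2r1	0.049	0.35	0.026	Independent	False
% CM-TG	Fap	0.000035	0.50	0.076		False
% CM-TG	Gca	0.0000041	0.69	0.76		False
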